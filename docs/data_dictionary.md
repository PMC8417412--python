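# Cohort CSV data dictionary

One row per infant evaluated for late-onset sepsis (LOS). Header required;
comma-separated, UTF-8; column names and order exactly as below. Enumerated
values are lower-case. Optional laboratory fields left blank mean "not
measured" and propagate as *missing* markers, never as normal ones.
All window summaries cover the closed interval from 6 h before the sepsis
work-up (t = 0) to 24 h after it.

| column | type | units / values | notes |
|---|---|---|---|
| `patient_id` | string | — | opaque identifier, unique within a file |
| `cohort` | enum | `development`, `validation` | temporal split tag |
| `gestational_age_weeks` | float | weeks | at birth; must lie in [22, 44] |
| `corrected_ga_weeks` | float | weeks | corrected gestational age at work-up |
| `birthweight_g` | float | grams | |
| `sex` | enum | `f`, `m` | |
| `day_of_life` | int | days | at work-up |
| `central_line` | bool | `true`/`false` | central venous line present |
| `parenteral_nutrition` | bool | `true`/`false` | |
| `temp_min_c`, `temp_max_c` | float? | °C | window extrema |
| `hr_max_bpm` | float? | beats/min | window maximum |
| `glucose_max_mgdl` | float? | mg/dl | window maximum |
| `wbc_min`, `wbc_max` | float? | cells/mm³ | leukocyte window extrema |
| `anc_min`, `anc_max` | float? | cells/mm³ | absolute neutrophil extrema |
| `lymph_min` | float? | cells/mm³ | minimum lymphocyte count |
| `platelets_min` | float? | cells/mm³ | minimum platelet count |
| `crp_max_mgdl` | float? | mg/dl | maximal C-reactive protein in window |
| `nlr_max` | float? | ratio | maximal neutrophil-to-lymphocyte ratio; `inf` allowed (zero lymphocytes) |
| `health_score_0h`, `health_score_24h` | enum | `healthy`, `equivocal`, `sick` | blinded 3-level appearance grade |
| `culture_positive` | bool | `true`/`false` | final blood-culture result |
| `time_to_positivity_h` | float? | hours | blank iff culture negative |
| `sepsis` | bool | `true`/`false` | culture-confirmed LOS outcome; `true` requires `culture_positive=true` |

`float?` marks optional fields. Validation errors name the offending
1-based data row.

## Derived marker panel

| marker | definition (strict inequalities) |
|---|---|
| `crp_high` | CRP > 0.75 mg/dl |
| `nlr_high` | NLR > 1.5 |
| `crp_or_nlr` | `crp_high` OR `nlr_high` (three-valued OR) |
| `lymphopenia` | lymphocytes < 2,000/mm³ |
| `abnormal_neutrophils` | ANC < 1,800 or > 5,400/mm³ |
| `abnormal_wbc` | WBC < 5,000 or > 20,000/mm³ |
| `thrombocytopenia` | platelets < 150,000/mm³ |
| `hyperglycemia` | glucose > 108 mg/dl |
| `abnormal_temperature` | temperature < 36 °C or > 37.5 °C |
| `tachycardia` | heart rate > 186 bpm |
| `sick_appearing` | worst-in-window appearance grade is `sick` |
| `culture_positive_24h` | culture positive with time to positivity ≤ 24 h |

Values exactly at a cutoff are normal.
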