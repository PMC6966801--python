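# Registry table schema

Input and output tables are UTF-8 CSV with a header row; a missing value is
an empty cell. Only `trial_id` is mandatory (and must be unique); every
other column may be absent or empty, in which case the audit works with
what remains and records what it had to assume or why it gave up.
Unknown columns are preserved untouched as opaque metadata.

## Design columns

| column | type | meaning |
|---|---|---|
| `trial_id` | string, unique | row key |
| `alpha` | float in (0, 0.5] | planned type-I error rate |
| `sidedness` | `one` / `two` | significance-testing convention; if empty the audit assumes a configurable default (two-sided) and logs the assumption |
| `planned_power` | float in (0, 1) | power at the design effect |
| `design_effect` | float ≠ 0 | target effect; interpreted through `design_effect_scale` |
| `design_effect_scale` | `natural` / `log_ratio` | `natural`: value already on the analysis scale; `log_ratio`: value is a ratio (odds/hazard ratio) whose absolute log is the analysis-scale effect |
| `planned_total_n` | int > 0 | planned total sample size (descriptive; information is never derived from it) |
| `outcome_kind` | `binary` / `continuous` / `time_to_event` / `other` | primary outcome type |
| `measure` | `risk_difference` / `log_odds_ratio` | binary effect measure used when reconstructing from arm counts |
| `total_information` | float > 0 | explicit planned total information I_K; takes precedence over the value derived from (alpha, power, design effect) |

## Interim columns

| column | type | meaning |
|---|---|---|
| `estimate` | float | interim effect estimate (analysis scale, benefit-positive) |
| `se` | float > 0 | its standard error |
| `z_value` | float | interim test statistic (benefit-positive) |
| `p_value` | float in (0, 1) | reported p-value, exact only |
| `p_is_bound` | bool | true when the report prints only a bound ("<0.001"); such p-values are refused, never imputed |
| `info_fraction` | float in (0, 1) | information time t_k; a value in (1, 100] is auto-detected as a percentage, with a logged warning |
| `interim_n` | int > 0 | sample size at the interim look |
| `n_looks_planned` | int | planned number of futility looks |
| `n_looks_actual` | int | looks actually executed before stopping |

Optional arm-level summaries, used only when no direct interim statistic is
available: `events_treat`, `n_treat`, `events_ctrl`, `n_ctrl` (binary);
`mean_treat`, `mean_ctrl`, `sd_treat`, `sd_ctrl` plus the arm sizes
(continuous).

## Metadata columns

| column | type | meaning |
|---|---|---|
| `sponsor` | `industry` / `non_industry` | funding source |
| `dsmb` | bool | data safety and monitoring board present |
| `decision_maker` | categorical | who decided to stop |
| `reported_cp` | float in [0, 1] | conditional power printed by the authors, retained verbatim |
| `reported_cp_hypothesis` | categorical | the authors' stated future-data assumption, if any |
| `data_collection_continued` | bool | whether follow-up continued past the last interim analysis |

## Audit resolution order

For each row the audit resolves, in order: the interim Z
(`z_value` → `estimate`/`se` → exact `p_value` → arm-level summaries), the
information fraction (`info_fraction` → `interim_n`/`planned_total_n` →
SE-derived information over I_K), and the total information
(`total_information` → derived from alpha, power and design effect). A row
where any link in the chain is missing for both hypotheses audits as
`insufficient` (or `reported_only` when `reported_cp` is present); an
information fraction at or beyond 1 is flagged as beyond full information,
never clamped.
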