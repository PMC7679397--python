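"""Build personal verbal/attribute models and test cross-participant agreement.

Composes each participant's verbal model (additive word-embedding sums over
content words) and attribute model (within-participant standardized Likert
ratings), fuses them into multimodal similarity vectors, and measures how
much scenario structure participants share: Spearman RSA between every pair
of participants' multimodal models, with a t-test of the Fisher-z values
against zero.  Output: results/model_agreement.tsv.
"""

from pathlib import Path

import pandas as pd

from idiorsa.group import cross_participant_model_agreement
from idiorsa.pipeline import build_personal_models, cohort_data_from_synthetic
from idiorsa.synthetic import CohortConfig, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0

cohort = generate_cohort(CohortConfig(idiosyncrasy=0.5, seed=SEED))
data = cohort_data_from_synthetic(cohort)
models = build_personal_models(data)

mean_rho, sd_rho, t, p = cross_participant_model_agreement(models.multimodal_sims)
n = len(models.multimodal_sims)
table = pd.DataFrame(
    [
        ("n_pairs", n * (n - 1) // 2),
        ("mean_rho", round(mean_rho, 4)),
        ("sd_rho", round(sd_rho, 4)),
        ("t_fisher_z", round(t, 2)),
        ("p_two_tailed", p),
    ],
    columns=["quantity", "value"],
)
RESULTS.mkdir(exist_ok=True)
table.to_csv(RESULTS / "model_agreement.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(
    f"\nparticipants share substantial scenario structure "
    f"(mean pairwise rho {mean_rho:.2f} over {n*(n-1)//2} pairs) "
    f"while retaining person-specific components (lambda=0.5)."
)
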