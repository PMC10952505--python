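"""Group comparisons against a reference agonist.

One-way ANOVA gates Dunnett's multiple-comparison test: post-hoc
comparisons against the reference group are run only when the ANOVA F test
reaches P < alpha; otherwise every comparison is reported as not tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class ReferenceComparison:
    reference_id: str
    f_statistic: float
    p_anova: float
    tested: bool
    p_adjusted: dict = field(default_factory=dict)  # agonist -> float | None

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [
            a for a, p in self.p_adjusted.items()
            if p is not None and p < alpha
        ]


def compare_to_reference(
    groups: dict[str, np.ndarray],
    reference_id: str,
    alpha: float = 0.05,
) -> ReferenceComparison:
    """ANOVA-gated Dunnett comparisons of each group against the reference.

    ``groups`` maps agonist id to its per-replicate values.  Degenerate
    input (all values identical, so F is undefined) is reported as not
    tested rather than an error.
    """
    if reference_id not in groups:
        raise ValueError(f"reference {reference_id!r} not among groups")
    if len(groups) < 3:
        raise ValueError("need at least two groups besides the reference")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")

    others = [k for k in arrays if k != reference_id]
    not_tested = {k: None for k in others}

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0 or all(np.ptp(v) == 0 for v in arrays.values()):
        return ReferenceComparison(reference_id, 0.0, 1.0, False, not_tested)

    f_stat, p_anova = sps.f_oneway(*arrays.values())
    if not np.isfinite(f_stat) or p_anova >= alpha:
        return ReferenceComparison(
            reference_id, float(f_stat), float(p_anova), False, not_tested
        )

    # fixed generator: the multivariate-t integration is randomised QMC
    res = sps.dunnett(
        *[arrays[k] for k in others], control=arrays[reference_id],
        random_state=np.random.default_rng(0),
    )
    p_adj = {k: float(p) for k, p in zip(others, res.pvalue)}
    return ReferenceComparison(
        reference_id, float(f_stat), float(p_anova), True, p_adj
    )
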