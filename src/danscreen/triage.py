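"""Decision layer: gated two-group tests, replication, intersection, rescue.

This module turns the per-stage measurements into the pipeline's yes/no
decisions:

- a normality-gated two-group comparison (Shapiro-Wilk chooses Student's t
  or Mann-Whitney U; behavioral PI scores are always tested parametrically,
  as they are normally distributed);
- the replication gate — a candidate survives only if *both* its memory and
  its vesicle-marker phenotypes replicate in dedicated retests, in the
  expected direction;
- the cross-modality intersection of replicated screen survivors with the
  genes transcriptionally down-regulated in both whole-brain knockdown
  panels (the step that isolates a single downstream gene);
- ANOVA + Tukey based classifiers for overexpression rescue and double-
  knockdown epistasis experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "GroupComparison",
    "StageLedger",
    "STAGE_FLAGS",
    "two_group_test",
    "replication_gate",
    "intersect_candidates",
    "pairwise_posthoc",
    "classify_rescue",
    "classify_epistasis",
]

ALPHA = 0.05

#: Ledger flags in pipeline order.  Each flag requires its predecessor except
#: the two panel flags, which both hang off primary_concordant (panel genes
#: are the primary-screen survivors) and jointly gate final_candidate.
STAGE_FLAGS = (
    "in_catalog",
    "tested_primary",
    "primary_hit",
    "primary_concordant",
    "secondary_hit",
    "secondary_concordant",
    "replicated",
    "sa_kd_downregulated",
    "smc1_kd_downregulated",
    "final_candidate",
)

_CHAIN = {
    "tested_primary": "in_catalog",
    "primary_hit": "tested_primary",
    "primary_concordant": "primary_hit",
    "secondary_hit": "primary_concordant",
    "secondary_concordant": "secondary_hit",
    "replicated": "secondary_concordant",
    "sa_kd_downregulated": "primary_concordant",
    "smc1_kd_downregulated": "primary_concordant",
}


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group comparison."""

    test_used: str  # "students_t" or "mann_whitney"
    p_value: float
    direction: int  # sign of mean(b) - mean(a)
    n_a: int
    n_b: int
    statistic: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")


def two_group_test(
    a: Sequence[float], b: Sequence[float], force: str | None = None
) -> GroupComparison:
    """Two-tailed two-group test, parametric or nonparametric as appropriate.

    Unless ``force`` pins the test, Shapiro-Wilk at alpha = 0.05 on each
    group selects Student's t (both consistent with normality) or
    Mann-Whitney U otherwise.  Behavioral data should pass
    ``force='students_t'``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"two_group_test needs n >= 3 per group, got {a.size} and {b.size}"
        )
    if force not in (None, "students_t", "mann_whitney"):
        raise ValueError(f"unknown force option {force!r}")
    direction = int(np.sign(b.mean() - a.mean()))

    degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
    if degenerate:
        # no variance anywhere: identical constants are maximally non-
        # significant; distinct constants are handled by Mann-Whitney ranks
        if a[0] == b[0]:
            return GroupComparison(force or "students_t", 1.0, 0, a.size, b.size, 0.0)
        force = force or "mann_whitney"

    if force is None:
        normal = all(stats.shapiro(g).pvalue >= ALPHA for g in (a, b))
        test = "students_t" if normal else "mann_whitney"
    else:
        test = force

    if test == "students_t":
        res = stats.ttest_ind(a, b, equal_var=True)
        p = float(res.pvalue)
        statistic = float(res.statistic)
        if np.isnan(p):  # both groups constant and equal
            p, statistic = 1.0, 0.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        p = float(res.pvalue)
        statistic = float(res.statistic)
    return GroupComparison(test, min(p, 1.0), direction, a.size, b.size, statistic)


def replication_gate(
    memory_retest: GroupComparison,
    sv_retest: GroupComparison,
    expected_direction: int,
    alpha: float = ALPHA,
) -> bool:
    """True iff both retests are significant *and* in the expected direction.

    ``expected_direction`` is +1 for a high-memory / SV-increase candidate
    and -1 for a low-memory / SV-decrease candidate (comparisons are control
    vs knockdown, direction = sign of knockdown minus control).
    """
    if expected_direction not in (-1, 1):
        raise ValueError("expected_direction must be +1 or -1")
    return (
        memory_retest.p_value < alpha
        and sv_retest.p_value < alpha
        and memory_retest.direction == expected_direction
        and sv_retest.direction == expected_direction
    )


def intersect_candidates(
    replicated: Iterable[str], sa_down: Iterable[str], smc1_down: Iterable[str]
) -> set[str]:
    """Replicated screen survivors down-regulated in BOTH knockdown panels."""
    return set(replicated) & set(sa_down) & set(smc1_down)


# ---------------------------------------------------------------------------
# multi-group classifiers

def _dunn_pairwise(groups: Sequence[np.ndarray]) -> dict[tuple[int, int], float]:
    """Dunn's rank-based post hoc after Kruskal-Wallis, Bonferroni-adjusted.

    Written out here because no installed package exposes Dunn's z-test; uses
    the standard tie-corrected variance of mean rank differences.
    """
    k = len(groups)
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    out: dict[tuple[int, int], float] = {}
    m = k * (k - 1) // 2
    for i, j in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(i, j)] = min(1.0, p * m)
    return out


def pairwise_posthoc(
    groups: Sequence[Sequence[float]], method: str = "anova_tukey"
) -> dict[tuple[int, int], float]:
    """All pairwise adjusted p-values across groups.

    ``anova_tukey`` (default) runs Tukey's HSD; ``kruskal_dunn`` runs Dunn's
    test with Bonferroni adjustment.  Keys are index pairs (i, j), i < j.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 3 for g in arrays):
        raise InsufficientDataError("each group needs n >= 3")
    if method == "anova_tukey":
        res = stats.tukey_hsd(*arrays)
        return {
            (i, j): float(res.pvalue[i, j]) for i, j in combinations(range(len(arrays)), 2)
        }
    if method == "kruskal_dunn":
        return _dunn_pairwise(arrays)
    raise ValueError(f"unknown post hoc method {method!r}")


def classify_rescue(
    control: Sequence[float],
    kd: Sequence[float],
    oe: Sequence[float],
    kd_plus_oe: Sequence[float],
    method: str = "anova_tukey",
    alpha: float = ALPHA,
) -> str:
    """Classify an overexpression-rescue experiment.

    ``full_rescue``: the rescue genotype is indistinguishable from control but
    differs from the knockdown alone.  ``partial_rescue``: it differs from
    both, with its mean between theirs (the phenotype moved toward control
    but remained shifted).  Anything else is ``no_rescue``.
    """
    groups = [np.asarray(g, float) for g in (control, kd, oe, kd_plus_oe)]
    p = pairwise_posthoc(groups, method)
    ctrl_i, kd_i, rescue_i = 0, 1, 3
    p_vs_ctrl = p[(ctrl_i, rescue_i)]
    p_vs_kd = p[(kd_i, rescue_i)]
    if p_vs_ctrl >= alpha and p_vs_kd < alpha:
        return "full_rescue"
    between = (
        min(groups[ctrl_i].mean(), groups[kd_i].mean())
        < groups[rescue_i].mean()
        < max(groups[ctrl_i].mean(), groups[kd_i].mean())
    )
    if p_vs_ctrl < alpha and p_vs_kd < alpha and between:
        return "partial_rescue"
    return "no_rescue"


def classify_epistasis(
    control: Sequence[float],
    kd_a: Sequence[float],
    kd_b: Sequence[float],
    double_kd: Sequence[float],
    method: str = "anova_tukey",
    alpha: float = ALPHA,
) -> str:
    """Classify a double-knockdown epistasis experiment.

    ``same_pathway``: the double knockdown differs from control but from
    neither single knockdown (knocking down both is no different from
    knocking down either).  ``additive``: the double significantly exceeds
    both singles in the direction of the effect.  Otherwise ``other``.
    """
    groups = [np.asarray(g, float) for g in (control, kd_a, kd_b, double_kd)]
    p = pairwise_posthoc(groups, method)
    ctrl_i, a_i, b_i, dbl_i = 0, 1, 2, 3
    dbl_vs_ctrl = p[(ctrl_i, dbl_i)]
    dbl_vs_a = p[(a_i, dbl_i)]
    dbl_vs_b = p[(b_i, dbl_i)]
    if dbl_vs_ctrl < alpha and dbl_vs_a >= alpha and dbl_vs_b >= alpha:
        return "same_pathway"
    effect_dir = np.sign(groups[dbl_i].mean() - groups[ctrl_i].mean())
    exceeds_a = np.sign(groups[dbl_i].mean() - groups[a_i].mean()) == effect_dir
    exceeds_b = np.sign(groups[dbl_i].mean() - groups[b_i].mean()) == effect_dir
    if (
        effect_dir != 0
        and dbl_vs_ctrl < alpha
        and dbl_vs_a < alpha
        and dbl_vs_b < alpha
        and exceeds_a
        and exceeds_b
    ):
        return "additive"
    return "other"


# ---------------------------------------------------------------------------
# stage ledger

class StageLedger:
    """Per-gene pass/fail record across every triage stage.

    Flags are monotone along the pipeline: setting a flag requires its
    prerequisite, and ``final_candidate`` additionally requires both panel
    down-regulation flags.  :meth:`validate` re-checks the whole invariant.
    """

    def __init__(self, gene_ids: Iterable[str]):
        self._flags: dict[str, dict[str, bool]] = {
            g: {f: False for f in STAGE_FLAGS} for g in gene_ids
        }

    @property
    def gene_ids(self) -> list[str]:
        return list(self._flags)

    def set_flag(self, gene_id: str, flag: str, value: bool = True) -> None:
        if gene_id not in self._flags:
            raise ValidationError(f"unknown gene {gene_id!r}")
        if flag not in STAGE_FLAGS:
            raise ValidationError(f"unknown stage flag {flag!r}")
        self._flags[gene_id][flag] = bool(value)

    def get(self, gene_id: str, flag: str) -> bool:
        return self._flags[gene_id][flag]

    def genes_with(self, flag: str) -> set[str]:
        return {g for g, f in self._flags.items() if f[flag]}

    def finalize(self) -> None:
        """Derive final_candidate = replicated ∧ down in both panels."""
        for g, f in self._flags.items():
            f["final_candidate"] = (
                f["replicated"] and f["sa_kd_downregulated"] and f["smc1_kd_downregulated"]
            )
        self.validate()

    def validate(self) -> None:
        for g, f in self._flags.items():
            for flag, prereq in _CHAIN.items():
                if f[flag] and not f[prereq]:
                    raise ValidationError(
                        f"{g}: flag {flag!r} set without prerequisite {prereq!r}"
                    )
            if f["final_candidate"] and not (
                f["replicated"] and f["sa_kd_downregulated"] and f["smc1_kd_downregulated"]
            ):
                raise ValidationError(f"{g}: final_candidate without its prerequisites")

    def stage_counts(self) -> dict[str, int]:
        return {flag: len(self.genes_with(flag)) for flag in STAGE_FLAGS}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self._flags, orient="index").astype(bool)
        df.index.name = "gene_id"
        return df.reset_index()

    def to_tsv(self, path) -> None:
        self.to_frame().astype({f: int for f in STAGE_FLAGS}).to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "final_candidates": sorted(self.genes_with("final_candidate")),
            "counts": self.stage_counts(),
        }
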