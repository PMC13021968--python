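"""Expression re-validation: count-panel normalization, ratios, and ΔΔCt.

Candidate genes' transcriptional changes are re-measured on an nCounter-style
digital counting panel (whole-brain pan-neuronal knockdown vs control) and by
RT-qPCR.  Panel counts are normalized by geometric-mean scaling against a
fixed housekeeping set — for each sample j,

    s_j = gm(all samples' housekeeping geometric means) / gm(housekeeping in j)

and every count in sample j is multiplied by s_j, after which the
housekeeping geometric mean is identical across samples.  The expression
ratio is mean(knockdown) / mean(control) of normalized counts; significance
is a two-sided Welch t-test on log2(normalized + 1).  qPCR fold changes use
the standard 2^(-ΔΔCt) law with triplicate Ct values averaged first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateReferenceError,
    FormatError,
    InsufficientDataError,
    MissingReferenceError,
    NormalizationError,
    ValidationError,
)

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "CountPanel",
    "ExpressionResult",
    "QPCRRecord",
    "housekeeping_normalize",
    "expression_ratio_and_test",
    "panel_expression_results",
    "ddct_fold",
    "read_count_panel",
    "read_qpcr_table",
]

#: Housekeeping anchors: two classical qPCR references plus four genes highly
#: expressed and unchanged in the knockdown RNA-seq data (dicer2 is driven by
#: the GAL4/UAS system itself, so its level is genotype-independent).
DEFAULT_HOUSEKEEPING = ("alphaTub84B", "Gapdh2", "Act5C", "brp", "unc-104", "dicer2")

GROUPS = ("control", "kd")


@dataclass
class CountPanel:
    """Genes x samples raw counts with a designated housekeeping set."""

    genes: list[str]
    samples: list[tuple[str, str]]  # (sample_id, group)
    counts: np.ndarray  # shape (n_genes, n_samples)
    housekeeping: tuple[str, ...] = DEFAULT_HOUSEKEEPING

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        if not self.housekeeping:
            raise ValidationError("housekeeping set must be nonempty")
        missing = set(self.housekeeping) - set(self.genes)
        if missing:
            raise ValidationError(f"housekeeping genes absent from panel: {sorted(missing)}")
        for g, grp in self.samples:
            if grp not in GROUPS:
                raise ValidationError(f"sample {g}: group must be one of {GROUPS}, got {grp!r}")

    @property
    def hk_index(self) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.genes)}
        return np.array([idx[g] for g in self.housekeeping])

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([j for j, (_, g) in enumerate(self.samples) if g == group], dtype=int)


@dataclass(frozen=True)
class ExpressionResult:
    """Per-gene panel re-validation result."""

    gene_id: str
    expression_ratio: float
    p_value: float
    significant: bool
    concordant_with_rnaseq: bool = False


@dataclass(frozen=True)
class QPCRRecord:
    """One sample's triplicate Ct values for a target and a housekeeping gene."""

    sample_id: str
    group: str
    ct_target: tuple[float, float, float]
    ct_housekeeping: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name, trip in (("ct_target", self.ct_target), ("ct_housekeeping", self.ct_housekeeping)):
            arr = np.asarray(trip, dtype=float)
            if arr.shape != (3,):
                raise ValidationError(f"{self.sample_id}: {name} must be a triplicate")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValidationError(f"{self.sample_id}: {name} must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_housekeeping))


def housekeeping_normalize(panel: CountPanel) -> np.ndarray:
    """Geometric-mean housekeeping scaling; returns the normalized matrix.

    Raises :class:`NormalizationError` naming the first offending gene and
    sample when a housekeeping count is zero (its geometric mean would be 0).
    """
    hk = panel.counts[panel.hk_index, :]
    zero = np.argwhere(hk == 0)
    if zero.size:
        i, j = zero[0]
        raise NormalizationError(
            f"housekeeping gene {panel.housekeeping[i]!r} has count 0 in sample "
            f"{panel.samples[j][0]!r}"
        )
    log_gm = np.mean(np.log(hk), axis=0)  # per-sample log geometric mean
    grand = float(np.mean(log_gm))
    scale = np.exp(grand - log_gm)
    return panel.counts * scale[np.newaxis, :]


def expression_ratio_and_test(
    panel: CountPanel,
    gene: str,
    rnaseq_log2fc: float | None = None,
    alpha: float = 0.05,
    normalized: np.ndarray | None = None,
) -> ExpressionResult:
    """Knockdown/control expression ratio for one gene, with a Welch t-test.

    The ratio needs >= 1 sample per group; the test needs >= 2.  Concordance
    with the RNA-seq direction requires significance and a matching sign of
    the log ratio.
    """
    if normalized is None:
        normalized = housekeeping_normalize(panel)
    try:
        gi = panel.genes.index(gene)
    except ValueError:
        raise ValidationError(f"gene {gene!r} not on panel") from None
    ctrl = normalized[gi, panel.group_columns("control")]
    kd = normalized[gi, panel.group_columns("kd")]
    if ctrl.size < 1 or kd.size < 1:
        raise InsufficientDataError(f"{gene}: need >= 1 sample per group for a ratio")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise DegenerateReferenceError(f"{gene}: control mean is {ctrl_mean} <= 0")
    ratio = float(kd.mean()) / ctrl_mean
    if ctrl.size >= 2 and kd.size >= 2:
        _, p = stats.ttest_ind(np.log2(kd + 1.0), np.log2(ctrl + 1.0), equal_var=False)
        p_value = float(p)
    else:
        p_value = float("nan")
    significant = bool(p_value < alpha)
    concordant = bool(
        significant
        and rnaseq_log2fc is not None
        and rnaseq_log2fc != 0
        and np.sign(np.log2(ratio)) == np.sign(rnaseq_log2fc)
    )
    return ExpressionResult(gene, ratio, p_value, significant, concordant)


def panel_expression_results(
    panel: CountPanel,
    rnaseq_log2fc: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Expression results for every non-housekeeping gene on the panel."""
    normalized = housekeeping_normalize(panel)
    rnaseq_log2fc = rnaseq_log2fc or {}
    rows = []
    for gene in panel.genes:
        if gene in panel.housekeeping:
            continue
        res = expression_ratio_and_test(
            panel, gene, rnaseq_log2fc.get(gene), alpha, normalized=normalized
        )
        rows.append(
            {
                "gene_id": res.gene_id,
                "expression_ratio": res.expression_ratio,
                "p_value": res.p_value,
                "significant": res.significant,
                "concordant_with_rnaseq": res.concordant_with_rnaseq,
            }
        )
    return pd.DataFrame(rows)


def ddct_fold(records: Sequence[QPCRRecord]) -> pd.DataFrame:
    """2^(-ΔΔCt) fold change per sample for one target gene.

    ΔCt = mean triplicate target Ct - mean triplicate housekeeping Ct per
    sample; ΔΔCt subtracts the mean control ΔCt; fold = 2^(-ΔΔCt).  With a
    single control sample its own fold is exactly 1.
    """
    if not any(r.group == "control" for r in records):
        raise MissingReferenceError("ΔΔCt requires at least one control sample")
    if not any(r.group == "kd" for r in records):
        raise MissingReferenceError("ΔΔCt requires at least one knockdown sample")
    ctrl_dct = float(np.mean([r.delta_ct for r in records if r.group == "control"]))
    rows = []
    for r in records:
        ddct = r.delta_ct - ctrl_dct
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "delta_ct": r.delta_ct,
                "ddct": ddct,
                "fold": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers

def read_count_panel(
    counts_path,
    groups_path,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
) -> CountPanel:
    """Read a counts matrix (first column gene_id, header = sample ids) and a
    sidecar TSV mapping sample_id to group."""
    sep = "," if str(counts_path).endswith(".csv") else "\t"
    mat = pd.read_csv(counts_path, sep=sep, index_col=0)
    grp = pd.read_csv(groups_path, sep="\t", dtype=str)
    if set(grp.columns) < {"sample_id", "group"}:
        raise FormatError(f"{groups_path}: needs columns sample_id, group")
    mapping = dict(zip(grp["sample_id"], grp["group"]))
    missing = set(mat.columns) - set(mapping)
    if missing:
        raise FormatError(f"{groups_path}: no group for sample(s) {sorted(missing)}")
    samples = [(s, mapping[s]) for s in mat.columns]
    return CountPanel(list(mat.index.astype(str)), samples, mat.to_numpy(float), tuple(housekeeping))


def read_qpcr_table(path) -> dict[str, list[QPCRRecord]]:
    """Read a qPCR TSV (sample_id, group, replicate, ct_target, ct_housekeeping),
    optionally with a gene_id column; returns records grouped by gene."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "replicate", "ct_target", "ct_housekeeping"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if "gene_id" not in df.columns:
        df = df.assign(gene_id="target")
    out: dict[str, list[QPCRRecord]] = {}
    for (gene, sample, group), g in df.groupby(["gene_id", "sample_id", "group"], sort=True):
        g = g.sort_values("replicate")
        if len(g) != 3:
            raise ValidationError(f"{path}: sample {sample} ({gene}): expected a triplicate")
        out.setdefault(str(gene), []).append(
            QPCRRecord(
                str(sample),
                str(group),
                tuple(g["ct_target"].astype(float)),
                tuple(g["ct_housekeeping"].astype(float)),
            )
        )
    return out
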