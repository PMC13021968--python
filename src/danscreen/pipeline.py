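"""End-to-end orchestration: catalog -> screens -> retest -> expression -> intersection.

`run_study` drives the whole triage on in-memory tables (as produced by
:mod:`danscreen.synthetic` or read from disk) and returns the per-gene
:class:`~danscreen.triage.StageLedger` plus a JSON-serializable report.
`run_pipeline` is the file-based wrapper the CLI uses.

Gene-level aggregation over RNAi lines: a gene passes a stage if ANY of its
tested lines passes — screens are scored per line, but candidates are genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .behavior import read_primary_table, run_primary_screen
from .deg_catalog import (
    DEGRecord,
    RNAiCatalogEntry,
    catalog_accounting,
    read_catalog,
    read_deg_table,
    significant_degs,
)
from .errors import FormatError
from .expression import DEFAULT_HOUSEKEEPING, CountPanel, panel_expression_results, read_count_panel
from .sv_marker import read_roi_table, run_secondary_screen
from .triage import StageLedger, replication_gate, two_group_test
from .synthetic import SA_TARGET, SMC1_TARGET, SyntheticStudy

__all__ = ["RunConfig", "run_study", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative run configuration (YAML on disk; flags may override)."""

    deg_table: str
    catalog: str
    primary_screen: str
    secondary_screen: str
    retest_memory: str
    retest_sv: str
    panel_sa_counts: str
    panel_sa_groups: str
    panel_smc1_counts: str
    panel_smc1_groups: str
    output_dir: str = "danscreen_out"
    primary_threshold: float = 0.25
    secondary_threshold: float = 0.25
    alpha: float = 0.05
    housekeeping: list[str] = field(default_factory=lambda: list(DEFAULT_HOUSEKEEPING))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primary_threshold <= 0 or self.secondary_threshold <= 0:
            raise FormatError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise FormatError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _gene_calls(line_calls: pd.DataFrame) -> pd.DataFrame:
    """Aggregate line-level screen calls to gene level (ANY-line rule)."""
    if line_calls.empty:
        return pd.DataFrame(columns=["gene_id", "hit", "concordant", "hit_class"])
    rows = []
    for gene_id, grp in line_calls.groupby("gene_id", sort=True):
        conc = grp[grp["concordant"]]
        hit_rows = grp[grp["hit_class"] != "none"] if "hit_class" in grp else grp[grp["hit_direction"] != "none"]
        cls_col = "hit_class" if "hit_class" in grp else "hit_direction"
        rows.append(
            {
                "gene_id": gene_id,
                "hit": not hit_rows.empty,
                "concordant": not conc.empty,
                "hit_class": (conc.iloc[0][cls_col] if not conc.empty
                              else (hit_rows.iloc[0][cls_col] if not hit_rows.empty else "none")),
            }
        )
    return pd.DataFrame(rows)


def _panel_down_set(
    panel: CountPanel, log2fc: dict[str, float], alpha: float, target: str
) -> tuple[set[str], pd.DataFrame]:
    """Genes significantly reduced on a knockdown panel, excluding the
    knockdown target itself (which is only the manipulation check)."""
    results = panel_expression_results(panel, log2fc, alpha)
    down = set(
        results.loc[
            results["significant"]
            & (results["expression_ratio"] < 1.0)
            & (results["gene_id"] != target),
            "gene_id",
        ]
    )
    return down, results


def run_study(
    deg_records: list[DEGRecord],
    catalog: list[RNAiCatalogEntry],
    primary_table: pd.DataFrame,
    secondary_table: pd.DataFrame,
    retest_memory: pd.DataFrame,
    retest_sv: pd.DataFrame,
    panels: dict[str, CountPanel],
    primary_threshold: float = 0.25,
    secondary_threshold: float = 0.25,
    alpha: float = 0.05,
) -> tuple[StageLedger, dict]:
    """Run the full triage on in-memory tables.

    Returns the stage ledger and a report with per-stage counts, the final
    candidate set, the catalog accounting, and every parameter used.
    """
    degs = {r.gene_id: r for r in deg_records}
    sig = significant_degs(deg_records, alpha)
    accounting = catalog_accounting(set(degs), catalog)

    ledger = StageLedger(sorted(degs))
    tested_genes = {e.gene_id for e in catalog if e.tested}
    for e in catalog:
        if e.available:
            ledger.set_flag(e.gene_id, "in_catalog")
    for g in tested_genes:
        ledger.set_flag(g, "tested_primary")

    # primary behavioral screen
    warning = None
    if primary_table.empty:
        primary_line_calls = pd.DataFrame(
            columns=["gene_id", "line_id", "library", "n_replicates",
                     "trimmed_mean_pi", "memory_score", "hit_class", "concordant"]
        )
        trim_log: list[dict] = []
        warning = "primary screen table is empty; no candidates can be called"
    else:
        primary_line_calls, trim_log = run_primary_screen(
            primary_table, degs, primary_threshold, alpha
        )
    primary_genes = _gene_calls(primary_line_calls)
    gene_class = dict(zip(primary_genes["gene_id"], primary_genes["hit_class"]))
    for row in primary_genes.itertuples(index=False):
        if row.gene_id not in tested_genes:
            continue
        if row.hit:
            ledger.set_flag(row.gene_id, "primary_hit")
        if row.concordant:
            ledger.set_flag(row.gene_id, "primary_concordant")
    primary_concordant = ledger.genes_with("primary_concordant")

    # secondary vesicle-marker screen, restricted to primary survivors
    if not secondary_table.empty and primary_concordant:
        keep = secondary_table["gene_id"].isin(primary_concordant | {"control"})
        secondary_line_calls, _ = run_secondary_screen(
            secondary_table[keep],
            {g: gene_class[g] for g in primary_concordant},
            secondary_threshold,
        )
    else:
        secondary_line_calls = pd.DataFrame(
            columns=["gene_id", "line_id", "n_animals", "fi_ratio", "hit_direction", "concordant"]
        )
    secondary_genes = _gene_calls(secondary_line_calls)
    for row in secondary_genes.itertuples(index=False):
        if row.gene_id not in primary_concordant:
            continue
        if row.hit:
            ledger.set_flag(row.gene_id, "secondary_hit")
        if row.concordant:
            ledger.set_flag(row.gene_id, "secondary_concordant")
    secondary_concordant = ledger.genes_with("secondary_concordant")

    # replication retests (memory forced parametric; marker data gated)
    retest_stats = []
    for g in sorted(secondary_concordant):
        mem = retest_memory[retest_memory["gene_id"] == g]
        sv = retest_sv[retest_sv["gene_id"] == g]
        if mem.empty or sv.empty:
            continue
        mem_cmp = two_group_test(
            mem.loc[mem["group"] == "control", "pi"],
            mem.loc[mem["group"] == "kd", "pi"],
            force="students_t",
        )
        sv_cmp = two_group_test(
            sv.loc[sv["group"] == "control", "intensity"],
            sv.loc[sv["group"] == "kd", "intensity"],
        )
        expected = 1 if gene_class.get(g) == "high" else -1
        ok = replication_gate(mem_cmp, sv_cmp, expected, alpha)
        if ok:
            ledger.set_flag(g, "replicated")
        retest_stats.append(
            {
                "gene_id": g,
                "memory_test": mem_cmp.test_used,
                "memory_p": mem_cmp.p_value,
                "sv_test": sv_cmp.test_used,
                "sv_p": sv_cmp.p_value,
                "expected_direction": expected,
                "replicated": ok,
            }
        )

    # expression re-validation on the two knockdown panels
    log2fc = {g: r.log2fc for g, r in degs.items()}
    panel_results = {}
    down_sets = {}
    for key, target in (("sa", SA_TARGET), ("smc1", SMC1_TARGET)):
        if key in panels:
            down_sets[key], panel_results[key] = _panel_down_set(
                panels[key], log2fc, alpha, target
            )
        else:
            down_sets[key] = set()
    for key, flag in (("sa", "sa_kd_downregulated"), ("smc1", "smc1_kd_downregulated")):
        for g in down_sets[key] & primary_concordant:
            ledger.set_flag(g, flag)

    ledger.finalize()

    report = {
        "parameters": {
            "primary_threshold": primary_threshold,
            "secondary_threshold": secondary_threshold,
            "alpha": alpha,
        },
        "catalog_accounting": accounting,
        "n_significant_degs": len(sig),
        "stage_counts": ledger.stage_counts(),
        "final_candidates": sorted(ledger.genes_with("final_candidate")),
        "replicated": sorted(ledger.genes_with("replicated")),
        "sa_kd_down": sorted(down_sets["sa"]),
        "smc1_kd_down": sorted(down_sets["smc1"]),
        "retest_stats": retest_stats,
        "n_trim_decisions": len(trim_log),
    }
    if warning:
        report["warning"] = warning
    return ledger, report


def run_study_from_synthetic(study: SyntheticStudy, **kwargs) -> tuple[StageLedger, dict]:
    """Convenience: run the triage directly on a generated synthetic study."""
    return run_study(
        study.deg_records,
        study.catalog,
        study.primary_table,
        study.secondary_table,
        study.retest_memory,
        study.retest_sv,
        study.panels,
        **kwargs,
    )


def run_pipeline(config: RunConfig) -> tuple[StageLedger, dict]:
    """File-based full pipeline run; writes ledger TSV, report JSON, trim log.

    Outputs are written atomically at the end of a successful run, so a
    failing stage leaves no partial outputs behind.
    """
    deg_records = read_deg_table(config.deg_table)
    catalog = read_catalog(config.catalog)
    primary = read_primary_table(config.primary_screen)
    secondary = read_roi_table(config.secondary_screen)
    retest_memory = pd.read_csv(config.retest_memory, sep="\t", dtype={"gene_id": str})
    retest_sv = pd.read_csv(config.retest_sv, sep="\t", dtype={"gene_id": str})
    panels = {
        "sa": read_count_panel(config.panel_sa_counts, config.panel_sa_groups, config.housekeeping),
        "smc1": read_count_panel(
            config.panel_smc1_counts, config.panel_smc1_groups, config.housekeeping
        ),
    }
    ledger, report = run_study(
        deg_records,
        catalog,
        primary,
        secondary,
        retest_memory,
        retest_sv,
        panels,
        config.primary_threshold,
        config.secondary_threshold,
        config.alpha,
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger.to_tsv(outdir / "stage_ledger.tsv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return ledger, report
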