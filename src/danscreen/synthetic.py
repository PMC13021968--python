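"""Synthetic-study generator with planted ground truth.

Generates every input the triage pipeline consumes — DEG table, RNAi-line
catalog, primary behavioral screen, secondary vesicle-marker screen, retest
tables, two knockdown count panels, qPCR plates and shock-response traces —
from a single seeded configuration, with a known set of planted "downstream"
genes.  Planted genes are significantly down-regulated in the DEG table,
raise memory scores in the primary screen, raise the vesicle marker in the
secondary screen, replicate both phenotypes in retests, and are
down-regulated in both whole-brain knockdown panels, so the full pipeline
has a known answer.

The generator mirrors the screening study's accounting and structure: 160
DEGs (92 up / 68 down), 4 genes without RNAi lines, 6 genes whose only line
is lethal, a handful of genes with a second line, controls interleaved
day-by-day with a shared additive day effect, four data points per line
trimmed to three, six animals per line in the marker screen, and
negative-binomial panel counts with per-sample library-size factors that the
housekeeping normalization must absorb.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .deg_catalog import DEGRecord, RNAiCatalogEntry, write_deg_table
from .errors import ValidationError
from .expression import DEFAULT_HOUSEKEEPING, CountPanel
from .imaging import ShockProtocol, ShockTrace

__all__ = ["StudyConfig", "SyntheticStudy", "gen_study", "gen_traces", "SA_TARGET", "SMC1_TARGET"]

#: Panel manipulation-check genes (the knocked-down regulator itself); they are
#: planted down in their own panel but excluded from the candidate "down" sets.
SA_TARGET = "SA"
SMC1_TARGET = "SMC1"


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of the synthetic study; the seed fixes every draw.

    ``control_pi_sd`` is the assay standard deviation of a single half-vial
    PI measurement; a data point averages two counterbalanced halves.
    ``count_dispersion`` is the negative-binomial dispersion alpha
    (var = mu + alpha mu^2); the default 0.01 corresponds to a ~10-12%
    coefficient of variation, the scale expected when each panel replicate
    pools 150 brains.
    """

    seed: int = 0
    n_genes: int = 160
    n_planted_downstream: int = 5
    n_up_degs: int = 92
    control_pi_mean: float = 0.4
    control_pi_sd: float = 0.08
    pi_effect_size: float = 0.35  # relative shift of mean PI for planted genes
    day_effect_sd: float = 0.03
    false_signal_rate: float = 0.05  # non-planted genes with a real memory-only effect
    fi_effect_size: float = 0.5  # relative Syt:eGFP increase for planted genes
    fi_cv: float = 0.15
    hemisphere_cv: float = 0.05
    count_dispersion: float = 0.01  # NB alpha
    planted_expression_ratio: float = 0.5
    panel_n_per_group: int = 4
    panel_mean_count: float = 1500.0
    retest_n: int = 12
    screen_replicates: int = 4
    flies_per_half: int = 60
    n_screen_days: int = 30
    n_no_line_genes: int = 4
    n_lethal_genes: int = 6
    n_second_lines: int = 13
    # shock-trace model
    trace_noise_sd: float = 2.0  # additive noise, % dF/F
    trace_amp_pct: float = 40.0  # first-pulse response amplitude, % dF/F
    trace_decay: float = 0.8  # per-pulse geometric amplitude decay (control)
    trace_rise_s: float = 1.25
    trace_fall_s: float = 2.0
    trace_baseline_f: float = 100.0
    n_traces_per_group: int = 12

    def __post_init__(self) -> None:
        for name in ("control_pi_sd", "day_effect_sd", "fi_cv", "hemisphere_cv",
                     "count_dispersion", "trace_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("pi_effect_size", "fi_effect_size", "planted_expression_ratio"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if not 0 <= self.false_signal_rate <= 1:
            raise ValidationError("false_signal_rate must lie in [0, 1]")
        if self.n_planted_downstream > self.n_genes - self.n_no_line_genes - self.n_lethal_genes:
            raise ValidationError("too many planted genes for the catalog structure")


@dataclass
class SyntheticStudy:
    """All generated tables plus the ground truth."""

    config: StudyConfig
    truth: pd.DataFrame  # gene_id, is_planted_downstream, true_direction, true_expression_ratio
    deg_records: list[DEGRecord]
    catalog: list[RNAiCatalogEntry]
    primary_table: pd.DataFrame
    secondary_table: pd.DataFrame
    retest_memory: pd.DataFrame
    retest_sv: pd.DataFrame
    panels: dict[str, CountPanel]
    qpcr: pd.DataFrame

    @property
    def planted_genes(self) -> set[str]:
        return set(self.truth.loc[self.truth["is_planted_downstream"], "gene_id"])

    def write(self, outdir) -> dict:
        """Write every table in its consuming module's dialect + a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["deg_table"] = str(outdir / "deg_table.tsv")
        write_deg_table(self.deg_records, paths["deg_table"])

        paths["catalog"] = str(outdir / "catalog.tsv")
        pd.DataFrame(
            [
                {
                    "gene_id": e.gene_id,
                    "line_id": e.line_id,
                    "library": e.library,
                    "available": int(e.available),
                    "lethal": int(e.lethal),
                }
                for e in self.catalog
            ]
        ).to_csv(paths["catalog"], sep="\t", index=False)

        for name, df in (
            ("primary_screen", self.primary_table),
            ("secondary_screen", self.secondary_table),
            ("retest_memory", self.retest_memory),
            ("retest_sv", self.retest_sv),
            ("qpcr", self.qpcr),
            ("ground_truth", self.truth),
        ):
            paths[name] = str(outdir / f"{name}.tsv")
            df.to_csv(paths[name], sep="\t", index=False)

        for key, panel in self.panels.items():
            cpath = outdir / f"panel_{key}_counts.tsv"
            gpath = outdir / f"panel_{key}_groups.tsv"
            pd.DataFrame(
                panel.counts, index=pd.Index(panel.genes, name="gene_id"),
                columns=[s for s, _ in panel.samples],
            ).to_csv(cpath, sep="\t")
            pd.DataFrame(panel.samples, columns=["sample_id", "group"]).to_csv(
                gpath, sep="\t", index=False
            )
            paths[f"panel_{key}_counts"] = str(cpath)
            paths[f"panel_{key}_groups"] = str(gpath)

        manifest = {
            "config": asdict(self.config),
            "paths": paths,
            "planted_genes": sorted(self.planted_genes),
            "housekeeping": list(DEFAULT_HOUSEKEEPING),
        }
        # the on-disk manifest stores paths relative to itself, so the same
        # seed yields byte-identical output wherever the study is written
        on_disk = dict(manifest, paths={k: Path(v).name for k, v in paths.items()})
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(on_disk, fh, indent=2, sort_keys=True)
        return manifest


def _pi_to_counts(pi: float, n: int) -> tuple[int, int]:
    pi = float(np.clip(pi, -1.0, 1.0))
    n_minus = int(round(n * (1.0 + pi) / 2.0))
    return n_minus, n - n_minus


def gen_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:03d}" for i in range(1, config.n_genes + 1)]

    # --- catalog structure: no-line genes, lethal-only genes, planted genes
    perm = list(rng.permutation(genes))
    no_line = set(perm[: config.n_no_line_genes])
    lethal = set(perm[config.n_no_line_genes : config.n_no_line_genes + config.n_lethal_genes])
    testable = [g for g in perm if g not in no_line and g not in lethal]
    planted = set(testable[: config.n_planted_downstream])

    # --- ground truth and DEG table (all entries significant, as the DEG
    # table is itself the list of significant genes)
    n_down_needed = config.n_genes - config.n_up_degs
    non_planted = [g for g in genes if g not in planted]
    extra_down = set(rng.choice(non_planted, size=n_down_needed - len(planted), replace=False))
    false_memory = {
        g for g in non_planted if rng.random() < config.false_signal_rate
    }

    deg_records, truth_rows = [], []
    for g in genes:
        down = g in planted or g in extra_down
        magnitude = 1.0 + rng.uniform(0.0, 1.5) if g in planted else rng.uniform(0.3, 2.5)
        log2fc = -magnitude if down else magnitude
        padj = float(rng.uniform(1e-6, 0.049))
        deg_records.append(DEGRecord(g, float(log2fc), padj))
        truth_rows.append(
            {
                "gene_id": g,
                "is_planted_downstream": g in planted,
                "true_direction": "down" if down else "up",
                "true_expression_ratio": config.planted_expression_ratio if g in planted else 1.0,
                "false_memory_signal": g in false_memory,
            }
        )
    truth = pd.DataFrame(truth_rows)

    # --- catalog entries
    catalog: list[RNAiCatalogEntry] = []
    line_no = 0

    def new_line(g: str, library: str, lethal_flag: bool = False) -> None:
        nonlocal line_no
        line_no += 1
        catalog.append(RNAiCatalogEntry(g, f"L{line_no:03d}", library, True, lethal_flag))

    libraries = {g: str(rng.choice(["KK", "GD", "TRiP"], p=[0.70, 0.27, 0.03])) for g in genes}
    for g in genes:
        if g in no_line:
            continue
        new_line(g, libraries[g], lethal_flag=g in lethal)
    second_line_genes = rng.choice(
        [g for g in genes if g not in no_line and g not in lethal],
        size=config.n_second_lines,
        replace=False,
    )
    for g in second_line_genes:
        new_line(g, libraries[g])

    # --- behavioral effects per gene
    def memory_effect(g: str) -> float:
        if g in planted:
            return config.pi_effect_size
        if g in false_memory:
            return config.pi_effect_size * (1 if rng.random() < 0.5 else -1)
        return 0.0

    gene_effect = {g: memory_effect(g) for g in genes}
    half_sd = config.control_pi_sd
    day_effects = rng.normal(0.0, config.day_effect_sd, config.n_screen_days)

    def data_point(mean_pi: float, day: int) -> dict:
        halves = rng.normal(mean_pi + day_effects[day], half_sd, 2)
        a = _pi_to_counts(halves[0], config.flies_per_half)
        b = _pi_to_counts(halves[1], config.flies_per_half)
        return {
            "n_cs_minus_a": a[0],
            "n_cs_plus_a": a[1],
            "n_cs_minus_b": b[0],
            "n_cs_plus_b": b[1],
        }

    # --- primary screen table (tested lines only, controls interleaved)
    tested_lines = [e for e in catalog if e.tested]
    rows = []
    control_days: set[tuple[int, str]] = set()
    for entry in tested_lines:
        mean_pi = config.control_pi_mean * (1.0 + gene_effect[entry.gene_id])
        days = rng.choice(config.n_screen_days, size=config.screen_replicates, replace=False)
        for r, day in enumerate(days):
            rows.append(
                {
                    "line_id": entry.line_id,
                    "gene_id": entry.gene_id,
                    "library": entry.library,
                    "day": int(day),
                    "replicate_index": r,
                    **data_point(mean_pi, int(day)),
                }
            )
            control_days.add((int(day), entry.library))
    for day, library in sorted(control_days):
        for r in range(2):
            rows.append(
                {
                    "line_id": "control",
                    "gene_id": "control",
                    "library": library,
                    "day": day,
                    "replicate_index": r,
                    **data_point(config.control_pi_mean, day),
                }
            )
    primary_table = pd.DataFrame(rows)

    # --- secondary screen (Syt:eGFP marker, 6 animals, 2 hemispheres)
    def sv_mean(g: str) -> float:
        return 100.0 * (1.0 + (config.fi_effect_size if g in planted else 0.0))

    sv_rows = []
    n_animals = 6
    for entry in tested_lines:
        for a in range(n_animals):
            animal = rng.lognormal(np.log(sv_mean(entry.gene_id)), config.fi_cv)
            for hemi in ("left", "right"):
                sv_rows.append(
                    {
                        "animal_id": f"{entry.line_id}_a{a}",
                        "line_id": entry.line_id,
                        "gene_id": entry.gene_id,
                        "genotype": entry.line_id,
                        "region": "heel",
                        "hemisphere": hemi,
                        "mean_intensity": animal * rng.normal(1.0, config.hemisphere_cv),
                    }
                )
    for a in range(4 * n_animals):  # a larger pooled control group
        animal = rng.lognormal(np.log(100.0), config.fi_cv)
        for hemi in ("left", "right"):
            sv_rows.append(
                {
                    "animal_id": f"control_a{a}",
                    "line_id": "control",
                    "gene_id": "control",
                    "genotype": "control",
                    "region": "heel",
                    "hemisphere": hemi,
                    "mean_intensity": animal * rng.normal(1.0, config.hemisphere_cv),
                }
            )
    secondary_table = pd.DataFrame(sv_rows)

    # --- retests (memory and SV, for every gene; the pipeline uses them only
    # for the genes that survive the screens)
    point_sd = half_sd / np.sqrt(2.0)
    mem_rows, svr_rows = [], []
    for g in genes:
        mu_kd = config.control_pi_mean * (1.0 + gene_effect[g])
        for r in range(config.retest_n):
            mem_rows.append(
                {"gene_id": g, "group": "control", "replicate": r,
                 "pi": float(np.clip(rng.normal(config.control_pi_mean, point_sd), -1, 1))}
            )
            mem_rows.append(
                {"gene_id": g, "group": "kd", "replicate": r,
                 "pi": float(np.clip(rng.normal(mu_kd, point_sd), -1, 1))}
            )
        for r in range(config.retest_n):
            svr_rows.append(
                {"gene_id": g, "group": "control", "animal_id": f"{g}_c{r}",
                 "intensity": float(rng.lognormal(np.log(100.0), config.fi_cv))}
            )
            svr_rows.append(
                {"gene_id": g, "group": "kd", "animal_id": f"{g}_k{r}",
                 "intensity": float(rng.lognormal(np.log(sv_mean(g)), config.fi_cv))}
            )
    retest_memory = pd.DataFrame(mem_rows)
    retest_sv = pd.DataFrame(svr_rows)

    # --- count panels (SA-style and SMC1-style whole-brain knockdowns)
    def nb_draw(mean: np.ndarray) -> np.ndarray:
        if config.count_dispersion <= 0:
            return rng.poisson(mean).astype(float)
        r = 1.0 / config.count_dispersion
        return rng.negative_binomial(r, r / (r + mean)).astype(float)

    hk_means = {g: m for g, m in zip(
        DEFAULT_HOUSEKEEPING, (8000.0, 12000.0, 20000.0, 15000.0, 5000.0, 10000.0)
    )}
    panel_gene_means = {
        g: float(rng.lognormal(np.log(config.panel_mean_count), 0.6)) for g in genes
    }
    panels: dict[str, CountPanel] = {}
    for key, target in (("sa", SA_TARGET), ("smc1", SMC1_TARGET)):
        panel_genes = list(DEFAULT_HOUSEKEEPING) + [target] + genes
        means = np.array(
            [hk_means[g] for g in DEFAULT_HOUSEKEEPING]
            + [2000.0]
            + [panel_gene_means[g] for g in genes]
        )
        ratios = np.ones(len(panel_genes))
        ratios[len(DEFAULT_HOUSEKEEPING)] = config.planted_expression_ratio  # the target itself
        for i, g in enumerate(genes):
            if g in planted:
                ratios[len(DEFAULT_HOUSEKEEPING) + 1 + i] = config.planted_expression_ratio
        samples, cols = [], []
        for grp in ("control", "kd"):
            for s in range(config.panel_n_per_group):
                size_factor = rng.lognormal(0.0, 0.2)
                mu = means * (ratios if grp == "kd" else 1.0) * size_factor
                cols.append(nb_draw(mu))
                samples.append((f"{key}_{grp}{s + 1}", grp))
        counts = np.column_stack(cols)
        counts[counts == 0] = 1.0  # digital counting floor; keeps housekeeping positive
        panels[key] = CountPanel(panel_genes, samples, counts, DEFAULT_HOUSEKEEPING)

    # --- qPCR plates for the planted genes (control vs knockdown, triplicate)
    qpcr_rows = []
    target_delta = 5.0
    for g in sorted(planted):
        for grp, n_samp in (("control", 5), ("kd", 5)):
            shift = 0.0 if grp == "control" else -np.log2(config.planted_expression_ratio)
            for s in range(n_samp):
                hk_ct = rng.normal(15.0, 0.1)
                tg_ct = hk_ct + target_delta + shift + rng.normal(0.0, 0.1)
                for rep in range(3):
                    qpcr_rows.append(
                        {
                            "gene_id": g,
                            "sample_id": f"{g}_{grp}{s + 1}",
                            "group": grp,
                            "replicate": rep,
                            "ct_target": round(tg_ct + rng.normal(0.0, 0.05), 4),
                            "ct_housekeeping": round(hk_ct + rng.normal(0.0, 0.05), 4),
                        }
                    )
    qpcr = pd.DataFrame(qpcr_rows)

    return SyntheticStudy(
        config=config,
        truth=truth,
        deg_records=deg_records,
        catalog=catalog,
        primary_table=primary_table,
        secondary_table=secondary_table,
        retest_memory=retest_memory,
        retest_sv=retest_sv,
        panels=panels,
        qpcr=qpcr,
    )


def pulse_waveform(
    times: np.ndarray,
    onset: float,
    amplitude: float,
    rise_s: float,
    fall_s: float,
) -> np.ndarray:
    """Triangular response: linear rise over the pulse, linear decay after.

    The closed-form area of each pulse is amplitude x (rise + fall) / 2,
    which the trapezoidal AUC reproduces exactly when onset, peak and end
    fall on the sampling grid.
    """
    up = (times - onset) / rise_s
    down = 1.0 - (times - onset - rise_s) / fall_s
    return amplitude * np.clip(np.minimum(up, down), 0.0, 1.0)


def gen_traces(
    config: StudyConfig,
    group: str,
    protocol: ShockProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> list[ShockTrace]:
    """Generate shock-response fluorescence traces for one genotype group.

    ``control_like`` responses decay geometrically pulse to pulse (synaptic
    depression); ``kd_like`` responses stay at the first-pulse amplitude
    (sustained dopamine release from an enlarged vesicle pool).
    """
    if group not in ("control_like", "kd_like"):
        raise ValidationError(f"group must be control_like or kd_like, got {group!r}")
    protocol = protocol or ShockProtocol()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_frames = round(4.0 * 150.0)
    times = np.arange(n_frames) / 4.0
    from .imaging import shock_onsets  # local to avoid cycle at import time

    onsets = shock_onsets(protocol)
    traces = []
    for _ in range(config.n_traces_per_group):
        dff = np.zeros(n_frames)
        for k, onset in enumerate(onsets):
            amp = config.trace_amp_pct * (config.trace_decay**k if group == "control_like" else 1.0)
            dff += pulse_waveform(times, onset, amp, config.trace_rise_s, config.trace_fall_s)
        if config.trace_noise_sd > 0:
            dff += rng.normal(0.0, config.trace_noise_sd, n_frames)
        f = config.trace_baseline_f * (1.0 + dff / 100.0)
        traces.append(ShockTrace(tuple(np.maximum(f, 0.0)), 4.0, 150.0))
    return traces
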