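"""Worked example: the cohesin-downstream screen in Drosophila dopamine neurons.

The published screening campaign this pipeline models started from 160
dopamine-neuron DEGs under Stromalin (cohesin subunit) knockdown and
triaged them through a behavioral screen, a Syt:eGFP vesicle-marker screen,
replication retests and two whole-brain knockdown expression panels, ending
at the single gene Neprilysin 1 (Nep1).  This module encodes the per-gene
stage outcomes of that campaign — the printed gene sets and catalog
accounting — as ready-made inputs for the decision layer, so the pipeline's
bookkeeping can be exercised against known, externally reported results.

The underlying per-vial scores and raw fluorescence tables are not shipped;
only the per-gene outcomes are encoded.
"""

from __future__ import annotations

from .deg_catalog import RNAiCatalogEntry
from .triage import StageLedger

__all__ = [
    "GENES_WITHOUT_LINES",
    "LETHAL_LINE_GENES",
    "TRIP_LINE_GENES",
    "SECONDARY_DECREASE_GENES",
    "SECONDARY_INCREASE_GENES",
    "REPLICATED_GENES",
    "SA_KD_DOWN_GENES",
    "SMC1_KD_DOWN_GENES",
    "N_PRIMARY_LOW_CONCORDANT",
    "N_PRIMARY_HIGH_CONCORDANT",
    "example_catalog",
    "example_stage_ledger",
]

#: DEGs for which no inducible RNAi line existed in any library.
GENES_WITHOUT_LINES = ("CR44474", "CG6511", "Hsc20", "l(3)psg2")

#: Genes whose only RNAi line was lethal when driven in dopamine neurons.
LETHAL_LINE_GENES = ("Bap55", "Pop2", "ftz-f1", "CG8034", "Rpt1", "CG3529")

#: Genes whose lines came from the TRiP library rather than the VDRC.
TRIP_LINE_GENES = ("CR40450", "Sfp53D", "RNASEK", "CG4631", "CG31808")

#: Primary-screen concordant hit counts (low-memory x up-regulated,
#: high-memory x down-regulated): together the 37 genes entering the
#: secondary screen.
N_PRIMARY_LOW_CONCORDANT = 10
N_PRIMARY_HIGH_CONCORDANT = 27

#: Secondary-screen survivors: low-memory genes with a Syt:eGFP decrease and
#: high-memory genes with the expected Syt:eGFP increase (10 candidates).
SECONDARY_DECREASE_GENES = ("CG42336", "AP-1sigma")
SECONDARY_INCREASE_GENES = (
    "atms", "Elp1", "CG2278", "Su(z)12", "CG17698", "COX7C", "Nep1", "ttm2",
)

#: Candidates whose memory AND vesicle-marker phenotypes both replicated.
REPLICATED_GENES = ("Su(z)12", "CG17698", "COX7C", "Nep1", "ttm2")

#: Genes significantly reduced on the pan-neuronal Stromalin-knockdown panel
#: (non-target genes replicating the RNA-seq downregulation).
SA_KD_DOWN_GENES = ("Lkr", "Octbeta1R", "Nep1")

#: Genes replicating their transcriptional direction under SMC1 knockdown.
SMC1_KD_DOWN_GENES = (
    "Octbeta1R", "CG17698", "COX7C", "Nep1", "atms", "TfIIB", "tra2",
    "Cpsf160", "CG9008", "Ras64B", "CG15657",
)


def example_catalog(n_degs: int = 160) -> tuple[set[str], list[RNAiCatalogEntry]]:
    """The screen's catalog accounting as explicit records.

    Encodes: 160 DEGs; 4 genes with no line; 169 lines over 156 genes (13
    genes carried a second line from the same library); 6 lethal lines, each
    the sole line for its gene.  Which specific genes carried duplicate
    lines was not reported, so placeholders stand in for them; the aggregate
    accounting (169 obtained / 163 tested / 150 genes tested) is exact.
    """
    named = set(GENES_WITHOUT_LINES) | set(LETHAL_LINE_GENES) | set(TRIP_LINE_GENES)
    fillers = [f"deg{i:03d}" for i in range(1, n_degs - len(named) + 1)]
    degs = set(named) | set(fillers)

    catalog: list[RNAiCatalogEntry] = []
    line_no = 0

    def add(gene: str, library: str, lethal: bool = False) -> None:
        nonlocal line_no
        line_no += 1
        catalog.append(RNAiCatalogEntry(gene, f"line{line_no:03d}", library, True, lethal))

    for g in LETHAL_LINE_GENES:
        add(g, "KK", lethal=True)
    for g in TRIP_LINE_GENES:
        add(g, "TRiP")
    remaining = [g for g in sorted(degs) if g not in GENES_WITHOUT_LINES
                 and g not in LETHAL_LINE_GENES and g not in TRIP_LINE_GENES]
    for g in remaining:
        add(g, "KK")
    for g in remaining[:13]:  # second line, same library
        add(g, "KK")
    return degs, catalog


def example_stage_ledger() -> StageLedger:
    """Stage ledger over the named survivors of the published campaign.

    Only the genes named at the secondary stage and beyond are tracked
    individually (earlier stages are known as counts, not gene lists); all
    ten secondary candidates are marked through secondary_concordant, the
    five replicated genes through replicated, and the panel flags follow the
    two knockdown-panel down-sets.  Finalizing the ledger must single out
    Nep1.
    """
    genes = sorted(
        set(SECONDARY_DECREASE_GENES)
        | set(SECONDARY_INCREASE_GENES)
        | set(SA_KD_DOWN_GENES)
        | set(SMC1_KD_DOWN_GENES)
    )
    ledger = StageLedger(genes)
    secondary = set(SECONDARY_DECREASE_GENES) | set(SECONDARY_INCREASE_GENES)
    tracked_through_screens = secondary | set(SA_KD_DOWN_GENES) | set(SMC1_KD_DOWN_GENES)
    # every tracked gene was a 37-gene primary survivor (the panels measured
    # exactly those genes)
    for g in tracked_through_screens:
        for flag in ("in_catalog", "tested_primary", "primary_hit", "primary_concordant"):
            ledger.set_flag(g, flag)
    for g in secondary:
        ledger.set_flag(g, "secondary_hit")
        ledger.set_flag(g, "secondary_concordant")
    for g in REPLICATED_GENES:
        ledger.set_flag(g, "replicated")
    for g in SA_KD_DOWN_GENES:
        ledger.set_flag(g, "sa_kd_downregulated")
    for g in SMC1_KD_DOWN_GENES:
        ledger.set_flag(g, "smc1_kd_downregulated")
    ledger.finalize()
    return ledger
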