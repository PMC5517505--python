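"""Three-criteria key-gene screen over a comparison's DEG list.

A DEG is nominated as a key regulatory gene when it
(1) changes strongly enough (|log2 ratio| strictly greater than 1.5),
(2) belongs to at least one significantly enriched term (any namespace), and
(3) appears in a curated list of known-pathology genes.

``strict`` mode requires all three; ``any_two`` keeps the magnitude gate
mandatory and requires at least one of the other two. Network degree and
core number annotate the report and break ties but are not gates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrich import significant_terms
from .io import GeneSetCollection, MechanismGeneList, ValidationError
from .network import CoexpressionNetwork

#: fixed column order of the key-gene report table
KEYGENE_COLUMNS = (
    "gene_id", "log2_ratio", "passes_magnitude", "passes_pathway",
    "passes_mechanism", "degree", "core_number", "selected",
)

MODES = ("strict", "any_two")


def screen_key_genes(
    degs: pd.DataFrame,
    enriched: pd.DataFrame | list[pd.DataFrame],
    sets: GeneSetCollection,
    mech: MechanismGeneList | None,
    net: CoexpressionNetwork | None = None,
    mode: str = "strict",
    log2_ratio_gate: float = 1.5,
) -> pd.DataFrame:
    """One report row per DEG, flagged per criterion and per-mode selected.

    ``enriched`` may be a single enrichment table or a list of them (one per
    namespace). ``mech=None`` disables criterion 3, in which case selection
    reduces to magnitude AND pathway in both modes. Output is sorted by
    (selected desc, core_number desc, |log2_ratio| desc, gene id asc).
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    if mech is not None and len(mech) == 0:
        raise ValidationError("mechanism gene list is empty; pass None to disable criterion 3")

    tables = enriched if isinstance(enriched, list) else [enriched]
    pathway_genes: set[str] = set()
    for table in tables:
        for tid in significant_terms(table):
            pathway_genes |= sets.members(tid)

    if degs.empty:
        return pd.DataFrame(columns=KEYGENE_COLUMNS)

    genes = degs["gene_id"].to_numpy()
    l2r = degs["log2_ratio"].to_numpy(dtype=np.float64)
    passes_magnitude = np.abs(l2r) > log2_ratio_gate
    passes_pathway = np.array([g in pathway_genes for g in genes])
    if mech is None:
        passes_mechanism = np.zeros(len(genes), dtype=bool)
        selected = passes_magnitude & passes_pathway
    else:
        passes_mechanism = np.array([g in mech for g in genes])
        if mode == "strict":
            selected = passes_magnitude & passes_pathway & passes_mechanism
        else:
            selected = passes_magnitude & (passes_pathway | passes_mechanism)

    degree = np.zeros(len(genes), dtype=int)
    core = np.zeros(len(genes), dtype=int)
    if net is not None:
        degree = np.array([net.degree.get(g, 0) for g in genes])
        core = np.array([net.core_number.get(g, 0) for g in genes])

    report = pd.DataFrame({
        "gene_id": genes,
        "log2_ratio": l2r,
        "passes_magnitude": passes_magnitude,
        "passes_pathway": passes_pathway,
        "passes_mechanism": passes_mechanism,
        "degree": degree,
        "core_number": core,
        "selected": selected,
    })
    report["_abs"] = np.abs(report["log2_ratio"])
    report = report.sort_values(
        ["selected", "core_number", "_abs", "gene_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    return report.drop(columns="_abs").reset_index(drop=True)
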