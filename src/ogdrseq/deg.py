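"""RPKM quantification and replicate-free differential expression calling.

Expression is quantified as RPKM (reads per kilobase of transcript per
million mapped reads):

    rpkm[g, s] = 1e9 * counts[g, s] / (total_mapped_reads[s] * length[g])

With a single library per condition there are no replicates to estimate
dispersion from, so the per-gene test is the exact Poisson-ratio
(Audic-Claverie) test: conditional on the sum ``x + y``, the second count
follows a negative binomial law, and the two-sided p-value doubles the
smaller conditional tail. Benjamini-Hochberg controls the FDR across all
testable genes of a comparison, and a gene is called differentially
expressed when it passes both the fold-change gate (>= 2-fold by default)
and the FDR gate (<= 0.001 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, ValidationError

#: RPKM values are floored at this value before forming log2 ratios, keeping
#: ratios finite when one library has zero reads for a gene
RPKM_FLOOR = 0.01

#: fixed column order of the per-comparison DEG report table
DEG_COLUMNS = (
    "gene_id", "count_ref", "count_trt", "rpkm_ref", "rpkm_trt",
    "log2_ratio", "p_raw", "fdr", "direction",
)


@dataclass
class ExpressionMatrix:
    """RPKM expression values, genes x samples."""

    rpkm: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rpkm.columns)


def compute_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Apply the RPKM formula cell-wise; zero counts give zero RPKM."""
    counts = cm.counts.to_numpy(dtype=np.float64)
    denom = cm.totals.to_numpy(dtype=np.float64)[None, :] * cm.lengths.to_numpy(dtype=np.float64)[:, None]
    rpkm = 1e9 * counts / denom
    return ExpressionMatrix(rpkm=pd.DataFrame(rpkm, index=cm.counts.index, columns=cm.counts.columns))


def ac_test(x, y, n1, n2):
    """Exact Poisson-ratio test for one count per library (two-sided).

    Under the null of equal underlying rates, conditioning on ``x``, the
    count ``y`` follows

        p(y | x) = (n2/n1)^y * (x+y)! / (x! * y! * (1 + n2/n1)^(x+y+1)),

    which is the negative binomial law ``NB(x + 1, n1/(n1+n2))``. The
    two-sided p-value is ``min(1, 2 * min(P(Y <= y), P(Y >= y)))``, evaluated
    through the regularized incomplete beta function for numerical stability.
    Accepts scalars or arrays; returns a float for scalar input.

    Parameters
    ----------
    x, y
        Read counts of the gene in the two libraries (nonnegative integers).
    n1, n2
        Total mapped reads of the two libraries (positive).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("counts must be nonnegative")
    if np.any(np.asarray(n1) <= 0) or np.any(np.asarray(n2) <= 0):
        raise ValidationError("library totals must be positive")
    q = np.asarray(n1, dtype=np.float64) / (np.asarray(n1, dtype=np.float64) + np.asarray(n2, dtype=np.float64))
    lower = stats.nbinom.cdf(y, x + 1, q)
    upper = stats.nbinom.sf(y - 1, x + 1, q)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if p.ndim == 0 else p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def differential_stats(
    em: ExpressionMatrix,
    cm: CountMatrix,
    treatment: str,
    reference: str,
    rpkm_floor: float = RPKM_FLOOR,
) -> pd.DataFrame:
    """Per-gene statistics for one treatment-vs-reference comparison.

    Returns one row per gene in input order with the :data:`DEG_COLUMNS`
    columns plus a ``tested`` flag. Genes with zero counts in both samples
    are untestable: they get ``p_raw = fdr = 1`` and are excluded from the
    BH denominator.
    """
    if treatment == reference:
        raise ValidationError("treatment and reference must differ")
    for s in (treatment, reference):
        if s not in cm.sample_ids:
            raise ValidationError(f"unknown sample id {s!r}")

    x = cm.counts[reference].to_numpy(dtype=np.int64)
    y = cm.counts[treatment].to_numpy(dtype=np.int64)
    n1 = int(cm.totals[reference])
    n2 = int(cm.totals[treatment])

    tested = (x + y) > 0
    p_raw = np.ones(len(x))
    p_raw[tested] = ac_test(x[tested], y[tested], n1, n2)
    fdr = np.ones(len(x))
    fdr[tested] = bh_adjust(p_raw[tested])

    rpkm_ref = em.rpkm[reference].to_numpy()
    rpkm_trt = em.rpkm[treatment].to_numpy()
    log2_ratio = np.log2(np.maximum(rpkm_trt, rpkm_floor) / np.maximum(rpkm_ref, rpkm_floor))

    return pd.DataFrame({
        "gene_id": cm.gene_ids,
        "count_ref": x,
        "count_trt": y,
        "rpkm_ref": rpkm_ref,
        "rpkm_trt": rpkm_trt,
        "log2_ratio": log2_ratio,
        "p_raw": p_raw,
        "fdr": fdr,
        "direction": np.where(log2_ratio > 0, "up", "down"),
        "tested": tested,
    })


def call_degs(
    em: ExpressionMatrix,
    cm: CountMatrix,
    treatment: str,
    reference: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.001,
    rpkm_floor: float = RPKM_FLOOR,
) -> pd.DataFrame:
    """Call differentially expressed genes between two samples.

    A gene is a DEG when ``|log2_ratio| >= log2(fc_threshold)`` and
    ``fdr <= fdr_threshold``. Records are sorted by fdr ascending, then
    ``|log2_ratio|`` descending, ties broken by gene id, and carry the
    :data:`DEG_COLUMNS` columns.
    """
    table = differential_stats(em, cm, treatment, reference, rpkm_floor=rpkm_floor)
    gate = (np.abs(table["log2_ratio"]) >= np.log2(fc_threshold)) & (table["fdr"] <= fdr_threshold)
    degs = table.loc[gate].copy()
    degs["_abs"] = np.abs(degs["log2_ratio"])
    degs = degs.sort_values(
        ["fdr", "_abs", "gene_id"], ascending=[True, False, True], kind="mergesort"
    )
    return degs.drop(columns=["_abs", "tested"]).reset_index(drop=True)
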