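"""NSAF quantification and differential-abundance calls.

Spectral counts are a label-free abundance proxy: longer and more abundant
proteins yield more peptide-spectrum matches. The normalized spectral
count of protein i in a pool is the NSAF

    nsc_i = (sc_i / L_i) / sum_j (sc_j / L_j)

where sc is the spectral count and L the protein length in amino acids;
values sum to 1 within each pool. Differential abundance between the ROS+
and ROS− pools is the ratio nsc_plus/nsc_minus (log2-transformed for
reporting); a 2-fold change is called significant, matching the 10–20%
precision typical of single-run spectral counting. Proteins observed in
only one pool are reported as unique to that pool rather than given an
infinite ratio.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from seminoquant.cohort_qc import RosGroup
from seminoquant.psm_io import ProteinEvidence, ProteinRecord

FOLD_THRESHOLD_DEFAULT = 2.0


class Call(str, enum.Enum):
    UNIQUE_ROS_MINUS = "unique_ROS_minus"
    UNIQUE_ROS_PLUS = "unique_ROS_plus"
    OVEREXPRESSED = "overexpressed"
    UNDEREXPRESSED = "underexpressed"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class QuantRow:
    """Per-protein quantification across the two pools.

    ``nsc_ratio`` and ``log2_nsc`` are None for pool-unique proteins.
    """

    protein_accession: str
    sc_minus: int
    sc_plus: int
    nsc_minus: float
    nsc_plus: float
    nsc_ratio: float | None
    log2_nsc: float | None
    call: Call


def nsaf(counts, lengths, method: str = "nsaf") -> np.ndarray:
    """Normalize spectral counts by protein length.

    ``"nsaf"``: (sc/L) renormalized to sum 1 over the pool.
    ``"sc_per_len_total"``: sc / (L × total spectral count) — the same
    length-and-depth correction without the renormalization step, so
    values do not sum to 1 but ratios between pools are depth-corrected.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(lengths < 1):
        raise ValueError("all protein lengths must be >= 1")
    if np.any(counts < 0):
        raise ValueError("spectral counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero spectral counts: nothing to normalize")
    saf = counts / lengths
    if method == "nsaf":
        return saf / saf.sum()
    if method == "sc_per_len_total":
        return saf / total
    raise ValueError(f"unknown normalization method {method!r}")


def nsc_ratio_log2(nsc_plus: float, nsc_minus: float) -> tuple[float, float]:
    """(ratio, log2 ratio) of normalized spectral counts, ROS+ over ROS−.

    Both inputs must be positive; a zero means the protein is unique to
    one pool and must be handled as such, not as a ratio.
    """
    if nsc_plus <= 0 or nsc_minus <= 0:
        raise ValueError(
            "nsc_ratio_log2 requires positive NSC in both pools; "
            "zero counts indicate a pool-unique protein"
        )
    ratio = nsc_plus / nsc_minus
    return ratio, math.log2(ratio)


def classify(
    sc_minus: int,
    sc_plus: int,
    nsc_ratio: float | None = None,
    fold_threshold: float = FOLD_THRESHOLD_DEFAULT,
) -> Call:
    """Differential call from pool counts and the NSC ratio.

    A protein absent from one pool is unique to the other. Otherwise the
    ratio is compared to the fold threshold: >= threshold is
    overexpressed (in ROS+), <= 1/threshold underexpressed, in between
    unchanged. Equivalent to |log2 ratio| >= log2(threshold).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if sc_minus < 0 or sc_plus < 0:
        raise ValueError("spectral counts must be non-negative")
    if sc_minus == 0 and sc_plus == 0:
        raise ValueError("protein has no spectra in either pool")
    if sc_minus == 0:
        return Call.UNIQUE_ROS_PLUS
    if sc_plus == 0:
        return Call.UNIQUE_ROS_MINUS
    if nsc_ratio is None:
        raise ValueError("nsc_ratio required when both counts are positive")
    if nsc_ratio >= fold_threshold:
        return Call.OVEREXPRESSED
    if nsc_ratio <= 1.0 / fold_threshold:
        return Call.UNDEREXPRESSED
    return Call.UNCHANGED


def build_comparison_table(
    evidence: list[ProteinEvidence],
    proteins: dict[str, ProteinRecord],
    norm: str = "nsaf",
    fold_threshold: float = FOLD_THRESHOLD_DEFAULT,
    pseudocount: float = 0.0,
) -> list[QuantRow]:
    """Quantify every protein with evidence in at least one pool.

    Normalization runs within each pool over all quantified proteins (a
    zero count contributes zero NSC). ``pseudocount`` > 0 is added to
    every count before normalization to shrink extreme ratios; calls for
    pool-unique proteins are still made from the raw counts.

    Rows are ordered ROS−-unique, then ROS+-unique (each by decreasing
    NSC in their pool), then common proteins by decreasing NSC ratio.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    sc: dict[str, dict[RosGroup, int]] = {}
    for ev in evidence:
        if ev.protein_accession not in proteins:
            raise ValueError(f"unknown protein {ev.protein_accession}")
        sc.setdefault(ev.protein_accession, {})[ev.pool] = ev.n_spectra
    if not sc:
        return []
    accessions = sorted(sc)
    lengths = np.array([proteins[a].length for a in accessions], dtype=float)
    raw_minus = np.array(
        [sc[a].get(RosGroup.ROS_MINUS, 0) for a in accessions], dtype=float
    )
    raw_plus = np.array(
        [sc[a].get(RosGroup.ROS_PLUS, 0) for a in accessions], dtype=float
    )
    def pool_nsc(raw: np.ndarray) -> np.ndarray:
        if raw.sum() == 0:  # pool empty: no identification in it at all
            return np.zeros_like(raw)
        return nsaf(raw + pseudocount, lengths, method=norm)

    nsc_minus = pool_nsc(raw_minus)
    nsc_plus = pool_nsc(raw_plus)

    rows: list[QuantRow] = []
    for i, accession in enumerate(accessions):
        s_minus, s_plus = int(raw_minus[i]), int(raw_plus[i])
        call = classify(s_minus, s_plus, None, fold_threshold) \
            if (s_minus == 0 or s_plus == 0) else None
        if call is None:
            ratio, log2r = nsc_ratio_log2(nsc_plus[i], nsc_minus[i])
            call = classify(s_minus, s_plus, ratio, fold_threshold)
        else:
            ratio = log2r = None
        rows.append(
            QuantRow(
                protein_accession=accession,
                sc_minus=s_minus,
                sc_plus=s_plus,
                nsc_minus=float(nsc_minus[i]),
                nsc_plus=float(nsc_plus[i]),
                nsc_ratio=ratio,
                log2_nsc=log2r,
                call=call,
            )
        )

    def sort_key(row: QuantRow):
        if row.call is Call.UNIQUE_ROS_MINUS:
            return (0, -row.nsc_minus, row.protein_accession)
        if row.call is Call.UNIQUE_ROS_PLUS:
            return (1, -row.nsc_plus, row.protein_accession)
        return (2, -row.nsc_ratio, row.protein_accession)

    return sorted(rows, key=sort_key)
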