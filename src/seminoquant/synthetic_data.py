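"""Synthetic cohorts, proteomes, digests and two-engine PSM tables.

The generator emulates a pooled two-group (ROS+/ROS−) spectral-counting
experiment with known ground truth so every pipeline stage can be
validated end to end:

* random protein sequences over the 20 amino acids;
* in-silico tryptic digestion (cleave after K/R unless followed by P);
* per-protein spectral counts drawn Poisson with expectation
  depth × abundance × length / Σ(abundance × length) — the generative
  premise under which NSAF is the matched, unbiased estimator of
  relative abundance;
* two imperfect search engines that each observe every spectrum
  independently with a configurable detection probability;
* a sample-metadata cohort with long-tailed ROS values and injected
  Endtz-positive specimens.

True fold changes are assigned in a compositionally balanced design:
for each effect magnitude m, every protein raised 2^m-fold is offset by
2^m proteins lowered 2^m-fold, so total abundance mass is conserved and
the relative-abundance ratio of an unchanged protein is exactly 1.
Without this balance, closed (compositional) normalization shifts every
apparent ratio by the net mass change and "unchanged" loses its meaning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seminoquant.cohort_qc import RosGroup
from seminoquant.psm_io import PSM_COLUMNS, Engine, ProteinRecord
from seminoquant.spectral_quant import Call

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CLEAVAGE = re.compile(r"[KR](?!P)")

MIN_PEPTIDE_LENGTH_DEFAULT = 6


@dataclass(frozen=True)
class Peptide:
    """One tryptic fragment with 1-based closed coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0


@dataclass
class SimConfig:
    """Study conditions for one simulated pooled experiment.

    depth is the expected total number of spectra per pool;
    detect_prob_a/b are per-spectrum engine detection probabilities;
    effect magnitudes are |log2| fold changes assigned in the balanced
    design described in the module docstring (frac_changed_per_magnitude
    gives, per magnitude m, the fraction of proteins raised 2^m-fold —
    each is offset by 2^m lowered proteins). An explicit ``log2_effects``
    array overrides the balanced design.
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (100, 400)
    depth: float = 50_000.0
    frac_changed_per_magnitude: dict[int, float] = field(
        default_factory=lambda: {1: 0.08, 2: 0.04}
    )
    log2_effects: np.ndarray | None = None
    unique_minus_frac: float = 0.03
    unique_plus_frac: float = 0.03
    abundance_sigma: float = 0.0  # SD of log base abundance; 0 = equal
    detect_prob_a: float = 0.95
    detect_prob_b: float = 0.90
    min_peptide_length: int = MIN_PEPTIDE_LENGTH_DEFAULT
    missed_cleavages: int = 0
    length_exponent: float = 1.0  # count expectation ∝ abundance × length^exp
    n_donors: int = 20
    n_patients: int = 32
    endtz_positive_rate: float = 0.075
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo < 7:
            raise ValueError(
                "minimum protein length must be >= 7 so tryptic peptides "
                "are producible"
            )
        if hi < lo:
            raise ValueError("length_range max must be >= min")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.unique_minus_frac < 1
                and 0 <= self.unique_plus_frac < 1
                and self.unique_minus_frac + self.unique_plus_frac < 1):
            raise ValueError("unique fractions must lie in [0,1) and sum < 1")
        for p in (self.detect_prob_a, self.detect_prob_b):
            if not 0 < p <= 1:
                raise ValueError("detection probabilities must be in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """True relative abundances per pool and the implied calls.

    ``rel_minus``/``rel_plus`` sum to 1 over the proteins present in
    that pool (0 marks absence). ``true_log2`` is
    log2(rel_plus/rel_minus) for proteins present in both pools, NaN
    otherwise.
    """

    accessions: tuple[str, ...]
    rel_minus: np.ndarray
    rel_plus: np.ndarray
    true_log2: np.ndarray
    true_call: tuple[Call, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_accession": self.accessions,
                "rel_minus": self.rel_minus,
                "rel_plus": self.rel_plus,
                "true_log2": self.true_log2,
                "true_call": [c.value for c in self.true_call],
            }
        )


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[Peptide]:
    """In-silico tryptic digestion with positional bookkeeping.

    Cleaves after K or R except when the next residue is P. All fully
    cleaved fragments are returned regardless of length, so concatenating
    the missed_cleavages==0 fragments reconstructs the sequence and
    coverage bookkeeping stays complete; use :func:`reportable_peptides`
    to apply the detectability length floor (default 6). Fragments
    spanning up to ``missed_cleavages`` skipped sites are appended after
    the fully cleaved ones.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    cut_after = [m.start() for m in _CLEAVAGE.finditer(sequence)]
    boundaries = [0] + [c + 1 for c in cut_after]
    if boundaries[-1] != len(sequence):
        boundaries.append(len(sequence))
    base: list[Peptide] = []
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        base.append(Peptide(sequence[b0:b1], b0 + 1, b1, 0))
    peptides = list(base)
    for k in range(1, missed_cleavages + 1):
        for i in range(len(base) - k):
            start = base[i].start
            end = base[i + k].end
            peptides.append(
                Peptide(sequence[start - 1:end], start, end, k)
            )
    return peptides


def reportable_peptides(
    peptides: list[Peptide], min_length: int = MIN_PEPTIDE_LENGTH_DEFAULT
) -> list[Peptide]:
    """Peptides long enough to be detected (length >= min_length)."""
    return [p for p in peptides if len(p.sequence) >= min_length]


def generate_proteome(
    config: SimConfig,
    rng: np.random.Generator,
    gene_symbols: list[str] | None = None,
) -> list[ProteinRecord]:
    """Random protein sequences with lengths uniform in ``length_range``."""
    n = config.n_proteins
    if gene_symbols is not None and len(gene_symbols) != n:
        raise ValueError("gene_symbols must match n_proteins")
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n):
        seq = "".join(rng.choice(alphabet, size=lengths[i]))
        gene = gene_symbols[i] if gene_symbols else f"GENE{i + 1:04d}"
        records.append(
            ProteinRecord(
                ncbi_accession=f"SYN{i + 1:06d}",
                gene_symbol=gene,
                uniprot_accession=f"U{i + 1:05d}",
                sequence=seq,
                description="synthetic protein",
            )
        )
    return records


def balanced_effects(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-protein true log2 effects under the balanced design.

    For each magnitude m, ``round(frac × n)`` proteins get +m and 2^m as
    many get −m, conserving total abundance mass when base abundances are
    equal. Remaining proteins are unchanged. Assignment order is
    randomized.
    """
    n = config.n_proteins
    effects: list[float] = []
    for magnitude, frac in sorted(config.frac_changed_per_magnitude.items()):
        n_up = int(round(frac * n))
        n_down = n_up * (2 ** magnitude)
        effects.extend([float(magnitude)] * n_up)
        effects.extend([-float(magnitude)] * n_down)
    if len(effects) > n:
        raise ValueError(
            "frac_changed_per_magnitude allocates more proteins than exist "
            f"({len(effects)} > {n}); lower the fractions"
        )
    effects.extend([0.0] * (n - len(effects)))
    arr = np.array(effects)
    rng.shuffle(arr)
    return arr


def generate_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw ground-truth relative abundances and calls for one experiment."""
    n = config.n_proteins
    if config.log2_effects is not None:
        effects = np.asarray(config.log2_effects, dtype=float)
        if effects.shape != (n,):
            raise ValueError("log2_effects must have length n_proteins")
    else:
        effects = balanced_effects(config, rng)
    base = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    n_um = int(round(config.unique_minus_frac * n))
    n_up = int(round(config.unique_plus_frac * n))
    order = rng.permutation(n)
    unique_minus_idx = order[:n_um]
    unique_plus_idx = order[n_um:n_um + n_up]
    present_minus = np.ones(n, dtype=bool)
    present_minus[unique_plus_idx] = False
    present_plus = np.ones(n, dtype=bool)
    present_plus[unique_minus_idx] = False
    effects = effects.copy()
    effects[~(present_minus & present_plus)] = 0.0  # uniques carry no fold change

    rel_minus = np.where(present_minus, base, 0.0)
    rel_minus /= rel_minus.sum()
    rel_plus = np.where(present_plus, base * np.power(2.0, effects), 0.0)
    rel_plus /= rel_plus.sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        true_log2 = np.where(
            present_minus & present_plus,
            np.log2(rel_plus / rel_minus),
            np.nan,
        )
    calls = []
    for i in range(n):
        if not present_plus[i]:
            calls.append(Call.UNIQUE_ROS_MINUS)
        elif not present_minus[i]:
            calls.append(Call.UNIQUE_ROS_PLUS)
        elif true_log2[i] >= 1.0 - 1e-12:
            calls.append(Call.OVEREXPRESSED)
        elif true_log2[i] <= -1.0 + 1e-12:
            calls.append(Call.UNDEREXPRESSED)
        else:
            calls.append(Call.UNCHANGED)
    accessions = tuple(f"SYN{i + 1:06d}" for i in range(n))
    return GroundTruth(
        accessions=accessions,
        rel_minus=rel_minus,
        rel_plus=rel_plus,
        true_log2=true_log2,
        true_call=tuple(calls),
    )


def generate_psms(
    proteome: list[ProteinRecord],
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[Engine, pd.DataFrame]:
    """Simulate the two engines' PSM tables for both pools.

    Per pool, protein counts are Poisson with mean
    depth × rel_abundance × length^e / Σ(rel_abundance × length^e); each
    spectrum is assigned a random reportable tryptic peptide of its
    protein and observed by each engine independently with that engine's
    detection probability.
    """
    lengths = np.array([p.length for p in proteome], dtype=float)
    digests = []
    for p in proteome:
        reportable = reportable_peptides(
            tryptic_digest(p.sequence, missed_cleavages=config.missed_cleavages),
            config.min_peptide_length,
        )
        if not reportable:  # pathologically cleavable protein: keep longest
            all_peps = tryptic_digest(p.sequence)
            reportable = [max(all_peps, key=lambda q: len(q.sequence))]
        digests.append(
            (
                np.array([q.sequence for q in reportable], dtype=object),
                np.array([q.start for q in reportable]),
                np.array([q.end for q in reportable]),
            )
        )

    columns: dict[Engine, dict[str, list]] = {
        e: {c: [] for c in PSM_COLUMNS} for e in Engine
    }
    detect_prob = {
        Engine.ENGINE_A: config.detect_prob_a,
        Engine.ENGINE_B: config.detect_prob_b,
    }
    for pool, rel in (
        (RosGroup.ROS_MINUS, truth.rel_minus),
        (RosGroup.ROS_PLUS, truth.rel_plus),
    ):
        weights = rel * np.power(lengths, config.length_exponent)
        weights = weights / weights.sum()
        counts = rng.poisson(config.depth * weights)
        for i, protein in enumerate(proteome):
            c = int(counts[i])
            if c == 0:
                continue
            pep_seqs, pep_starts, pep_ends = digests[i]
            pep_idx = rng.integers(0, len(pep_seqs), size=c)
            scores = np.round(rng.uniform(50.0, 2000.0, size=c), 1)
            spectrum_ids = np.array(
                [f"{pool.value}:{protein.ncbi_accession}:{k}" for k in range(c)],
                dtype=object,
            )
            for e in Engine:
                idx = np.nonzero(rng.random(c) < detect_prob[e])[0]
                if idx.size == 0:
                    continue
                col = columns[e]
                col["spectrum_id"].extend(spectrum_ids[idx])
                col["pool"].extend([pool.value] * idx.size)
                col["engine"].extend([e.value] * idx.size)
                col["peptide"].extend(pep_seqs[pep_idx[idx]])
                col["protein_accession"].extend(
                    [protein.ncbi_accession] * idx.size
                )
                col["score"].extend(scores[idx])
                col["start"].extend(pep_starts[pep_idx[idx]])
                col["end"].extend(pep_ends[pep_idx[idx]])
    return {e: pd.DataFrame(columns[e]) for e in Engine}


def generate_cohort(
    n_donors: int,
    n_patients: int,
    rng: np.random.Generator,
    ros_params: dict[str, tuple[float, float]] | None = None,
    endtz_positive_rate: float = 0.075,
) -> pd.DataFrame:
    """Simulate a sample-metadata table (the samples CSV schema).

    ROS values are log-normal with per-cohort (mu, sigma) on the log
    scale; defaults put the donor median near 4 and the patient median
    near 100 RLU/sec/10^6 sperm with a long right tail. Endtz-positive
    specimens (counts above 1×10^6/mL) are injected among patients at
    ``endtz_positive_rate``. Antioxidant capacity and DNA fragmentation
    are generated for patients only.
    """
    if n_donors < 0 or n_patients < 0:
        raise ValueError("cohort sizes must be non-negative")
    params = {"donor": (np.log(4.4), 2.5), "patient": (np.log(104.0), 2.2)}
    if ros_params:
        params.update(ros_params)
    rows = []
    specs = [("donor", n_donors), ("patient", n_patients)]
    counter = 0
    for cohort, count in specs:
        mu, sigma = params[cohort]
        for _ in range(count):
            counter += 1
            ros = float(rng.lognormal(mu, sigma))
            concentration = max(0.0, rng.normal(69.5 if cohort == "donor" else 42.9, 40.0))
            motility = float(np.clip(rng.normal(55.4 if cohort == "donor" else 49.1, 15.0), 0, 100))
            round_cells = max(0.0, rng.normal(2.9 if cohort == "donor" else 5.2, 2.4))
            morphology = float(np.clip(rng.normal(3.5, 2.5), 0, 100))
            endtz = 0.0
            if cohort == "patient" and rng.random() < endtz_positive_rate:
                endtz = float(rng.uniform(1.1, 2.5))
            tac = max(0.0, rng.normal(2000.0, 550.0)) if cohort == "patient" else ""
            dna = float(np.clip(rng.normal(20.0, 11.0), 0, 100)) if cohort == "patient" else ""
            rows.append(
                {
                    "subject_id": f"S{counter:03d}",
                    "cohort": cohort,
                    "concentration": round(concentration, 2),
                    "motility": round(motility, 1),
                    "round_cells": round(round_cells, 2),
                    "endtz": round(endtz, 2),
                    "morphology": round(morphology, 1),
                    "ros": round(ros, 1),
                    "tac": round(tac, 1) if tac != "" else "",
                    "dna_frag": round(dna, 1) if dna != "" else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "cohort", "concentration", "motility",
            "round_cells", "endtz", "morphology", "ros", "tac", "dna_frag",
        ],
    )


def simulate_experiment(
    config: SimConfig,
) -> tuple[list[ProteinRecord], GroundTruth, dict[Engine, pd.DataFrame], pd.DataFrame]:
    """Run the full generator from a config (deterministic given its seed)."""
    rng = np.random.default_rng(config.seed)
    proteome = generate_proteome(config, rng)
    truth = generate_truth(config, rng)
    psms = generate_psms(proteome, truth, config, rng)
    cohort = generate_cohort(
        config.n_donors, config.n_patients, rng,
        endtz_positive_rate=config.endtz_positive_rate,
    )
    return proteome, truth, psms, cohort


def simulate_to_dir(config: SimConfig, out_dir) -> dict[str, str]:
    """Write db.fasta, psm_a.tsv, psm_b.tsv, samples.csv and truth.tsv."""
    import os

    from seminoquant.psm_io import write_fasta

    os.makedirs(out_dir, exist_ok=True)
    proteome, truth, psms, cohort = simulate_experiment(config)
    paths = {
        "fasta": os.path.join(out_dir, "db.fasta"),
        "psm_a": os.path.join(out_dir, "psm_a.tsv"),
        "psm_b": os.path.join(out_dir, "psm_b.tsv"),
        "samples": os.path.join(out_dir, "samples.csv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_fasta(proteome, paths["fasta"])
    psms[Engine.ENGINE_A].to_csv(paths["psm_a"], sep="\t", index=False)
    psms[Engine.ENGINE_B].to_csv(paths["psm_b"], sep="\t", index=False)
    cohort.to_csv(paths["samples"], index=False)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
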