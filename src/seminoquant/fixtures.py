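"""Packaged reference fixtures: the printed study tables and a GO-slim map.

Three small TSVs ship with the package:

* ``reference_evidence.tsv`` — the per-pool identification evidence for the
  14 seminal-plasma proteins (distinct-peptide counts, sequence coverage
  and search-engine score per pool). Raw spectral counts were never
  published, so the peptide count serves as the per-pool count proxy;
  it preserves presence/absence exactly, which is all the set-structure
  analysis needs.
* ``published_quant.tsv`` — the published NSC ratios and log2 values for
  the seven proteins common to both pools, plus the pool-unique rows,
  stored verbatim (they cannot be re-derived without the raw counts).
* ``go_slim.tsv`` — generic GO-slim assignments for the 14 gene symbols,
  curated by the package authors from public GO resources; used to
  exercise the set-summary machinery, not to reproduce any published
  figure.

The two printed tables disagree on two accessions (clusterin 42716297 vs
355594753; semenogelin I isoform b 38049014 vs isoform a 4506883); each
fixture keeps its table's values verbatim and the gene symbols reconcile
them.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from seminoquant.annotation_enrichment import GOAnnotation, load_go_map
from seminoquant.cohort_qc import RosGroup
from seminoquant.psm_io import Engine, ProteinEvidence, ProteinRecord

_AVG_RESIDUE_MASS_KDA = 0.110  # average amino-acid residue mass


def _data_path(name: str):
    return files("seminoquant").joinpath("data").joinpath(name)


def reference_evidence() -> tuple[list[ProteinEvidence], dict[str, ProteinRecord]]:
    """Per-pool identification evidence for the 14 reference proteins.

    Returns (evidence rows, accession → protein record). Protein lengths
    are estimated from the printed molecular weights at 110 Da/residue
    (sequences were not published); the printed identifications are
    dual-engine validated, so every evidence row carries both engines.
    """
    with _data_path("reference_evidence.tsv").open() as handle:
        df = pd.read_csv(handle, sep="\t")
    proteins: dict[str, ProteinRecord] = {}
    evidence: list[ProteinEvidence] = []
    for row in df.itertuples(index=False):
        accession = str(row.ncbi_accession)
        proteins[accession] = ProteinRecord(
            ncbi_accession=accession,
            gene_symbol=row.gene,
            uniprot_accession=row.uniprot_accession,
            length=max(1, round(float(row.mw_kda) / _AVG_RESIDUE_MASS_KDA)),
            mw=float(row.mw_kda),
            pi=float(row.pi),
            description=row.protein_name,
        )
        for pool, pep_col, cov_col in (
            (RosGroup.ROS_MINUS, row.peptides_minus, row.coverage_minus),
            (RosGroup.ROS_PLUS, row.peptides_plus, row.coverage_plus),
        ):
            if pd.isna(pep_col):
                continue
            n_peptides = int(pep_col)
            evidence.append(
                ProteinEvidence(
                    protein_accession=accession,
                    pool=pool,
                    n_peptides=n_peptides,
                    n_spectra=n_peptides,  # count proxy: lower bound
                    engines=frozenset(Engine),
                    coverage=float(cov_col),
                )
            )
    return evidence, proteins


def published_quant() -> pd.DataFrame:
    """The published comparison table, verbatim.

    ``nsc_ratio`` is the string ``"ROS- only"``/``"ROS+ only"`` for
    pool-unique proteins and a number for the seven common ones.
    """
    with _data_path("published_quant.tsv").open() as handle:
        return pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)


def go_slim_annotations() -> list[GOAnnotation]:
    """Curated GO-slim assignments for the 14 reference gene symbols."""
    return load_go_map(_data_path("go_slim.tsv"))
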