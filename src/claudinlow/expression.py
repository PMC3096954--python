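"""Expression-matrix data model, preprocessing and file I/O.

The canonical in-memory container is a :class:`pandas.DataFrame` with gene
identifiers on the index, sample identifiers on the columns and ``NaN`` for
missing values — referred to throughout as an *expression matrix*.  Values are
log2 expression (for two-colour arrays, log2 Cy5/Cy3 ratios).

Preprocessing follows the standard two-colour microarray pipeline: probes are
intensity-filtered, probes mapping to the same gene are averaged into one
expression estimate per gene, genes are median-centered within a data set and
samples are standardized to zero mean and unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeTable",
    "GeneSignature",
    "validate_matrix",
    "preprocess_probe_table",
    "normalize_matrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
]


@dataclass
class ProbeTable:
    """Per-probe log2 ratios with the raw channel intensities.

    Parameters
    ----------
    log2_ratio : DataFrame, probes x samples
        Normalized log2 (sample / control) ratios; NaN = missing spot.
    sample_intensity, control_intensity : DataFrame, probes x samples
        Non-negative channel intensities, aligned to ``log2_ratio``.
    gene_map : Series, probe id -> gene id
        Probe-to-gene mapping (Entrez-style identifiers); probes absent from
        the map carry no annotation and are dropped during preprocessing.
    """

    log2_ratio: pd.DataFrame
    sample_intensity: pd.DataFrame
    control_intensity: pd.DataFrame
    gene_map: pd.Series

    def __post_init__(self) -> None:
        for name in ("sample_intensity", "control_intensity"):
            other = getattr(self, name)
            if not other.index.equals(self.log2_ratio.index) or not other.columns.equals(
                self.log2_ratio.columns
            ):
                raise ValueError(f"{name} is not aligned with log2_ratio")
            if (other.to_numpy() < 0).any():
                raise ValueError(f"{name} contains negative intensities")
        if self.gene_map.index.has_duplicates:
            raise ValueError("a probe maps to more than one gene id")


@dataclass
class GeneSignature:
    """A named gene set, optionally signed (up / down / unsigned)."""

    name: str
    gene_ids: tuple[str, ...]
    direction: str = "unsigned"
    down_gene_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"signature {self.name!r} has duplicate gene ids")
        if self.direction not in {"up", "down", "unsigned", "signed"}:
            raise ValueError(f"unknown direction {self.direction!r}")


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants (unique gene and sample ids)."""
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if m.columns.has_duplicates:
        dups = m.columns[m.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    return m


def preprocess_probe_table(probes: ProbeTable, intensity_threshold: float = 10.0) -> pd.DataFrame:
    """Intensity-filter probes and collapse them to one row per gene.

    A probe is kept iff its lowest sample intensity across arrays is above
    ``intensity_threshold`` AND its lowest control intensity across arrays is
    above the threshold.  Surviving probes of the same gene are averaged per
    sample, ignoring missing values; probes without a gene annotation are
    dropped (with a logged count), as are genes whose row is entirely missing.
    """
    if intensity_threshold <= 0:
        raise ValueError("intensity_threshold must be > 0")

    min_sample = probes.sample_intensity.min(axis=1, skipna=True)
    min_control = probes.control_intensity.min(axis=1, skipna=True)
    keep = (min_sample > intensity_threshold) & (min_control > intensity_threshold)
    ratios = probes.log2_ratio.loc[keep]

    annotated = ratios.index.intersection(probes.gene_map.index)
    n_unmapped = len(ratios) - len(annotated)
    if n_unmapped:
        logger.info("dropped %d probes without gene mapping", n_unmapped)
    ratios = ratios.loc[annotated]

    if ratios.empty:
        raise ValueError("no probes survive the intensity filter")

    genes = probes.gene_map.loc[ratios.index]
    collapsed = ratios.groupby(genes.to_numpy()).mean()
    collapsed = collapsed.dropna(how="all")
    if collapsed.empty:
        raise ValueError("no genes remain after collapsing probes")
    collapsed.index.name = "gene_id"
    return validate_matrix(collapsed)


def normalize_matrix(
    m: pd.DataFrame, center_genes: bool = True, standardize_samples: bool = True
) -> pd.DataFrame:
    """Median-center gene rows, then standardize sample columns.

    Gene centering subtracts each row's median (over non-missing values);
    sample standardization rescales each column to mean 0 and variance 1
    (population variance, ddof=0).  The order is center-then-standardize.
    """
    out = m.copy()
    if center_genes:
        out = out.sub(out.median(axis=1, skipna=True), axis=0)
    if standardize_samples:
        if out.shape[1] < 2:
            raise ValueError("standardization requires at least 2 samples")
        sd = out.std(axis=0, ddof=0, skipna=True)
        zero = sd[(sd == 0) | sd.isna()]
        if len(zero):
            raise ValueError(f"zero-variance sample column(s): {zero.index.tolist()}")
        out = out.sub(out.mean(axis=0, skipna=True), axis=1).div(sd, axis=1)
    return out


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a gene-by-sample TSV (gene-id first column, empty cell = missing)."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_fields:
                raise ValueError(f"{path}: ragged row at line {lineno}")
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    m.index.name = "gene_id"
    return validate_matrix(m)


def write_expression_tsv(m: pd.DataFrame, path) -> None:
    """Write an expression matrix as TSV (missing cells left empty)."""
    validate_matrix(m)
    out = m.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.8g")


def read_gmt(path) -> list[GeneSignature]:
    """Read GMT gene sets (name, description, then tab-separated gene ids).

    Duplicate gene ids within a set are removed (first occurrence kept) with
    a logged warning.
    """
    sigs: list[GeneSignature] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning("GMT set %r: removed %d duplicate ids", name, len(genes) - len(unique))
            sigs.append(GeneSignature(name=name, gene_ids=tuple(unique)))
    return sigs


def write_gmt(sigs: list[GeneSignature], path, description: str = "na") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for sig in sigs:
            fh.write("\t".join([sig.name, description, *sig.gene_ids]) + "\n")
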