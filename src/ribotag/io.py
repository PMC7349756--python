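"""Tabular input/output and the hybrid-genome data model.

A mixed-species co-culture experiment is described by four tables:

* a gene annotation table (:class:`GeneTable`) mapping each gene of the
  hybrid human+mouse reference (plus the GFP/mCherry reporter contigs) to
  its chromosome, species and Ensembl biotype;
* a gene-level count matrix in the featureCounts dialect, or per-sample
  chromosome-level count tables in the samtools-idxstats dialect;
* a sample sheet pairing each immunoprecipitation (IP) library with its
  matched co-culture input and declaring the antibody and on-target
  species.

All readers validate rather than repair: malformed or inconsistent rows
raise :class:`ValidationError`.  Every accepted file round-trips through
the matching writer.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GeneTable",
    "SampleSheet",
    "read_gene_table",
    "write_gene_table",
    "read_counts_featurecounts",
    "write_counts_featurecounts",
    "read_idxstats",
    "write_idxstats",
    "read_sample_sheet",
    "write_sample_sheet",
    "pair_samples",
    "write_table",
    "DEFAULT_MITO_NAMES",
]

#: Chromosome names recognised as mitochondrial.  Hybrid references often
#: prefix chromosomes with a species tag ("hs_MT"); matching also considers
#: the suffix after the last underscore.
DEFAULT_MITO_NAMES = frozenset({"MT", "chrM", "chrMT"})

#: Species label reserved for reporter transgene contigs (GFP, mCherry).
REPORTER_SPECIES = "reporter"


class ValidationError(ValueError):
    """An input table violates the data model."""


def _is_mito_name(chromosome: str, mito_names) -> bool:
    if chromosome in mito_names:
        return True
    if "_" in chromosome and chromosome.rsplit("_", 1)[1] in mito_names:
        return True
    return False


@dataclass
class GeneTable:
    """Per-gene annotation for a hybrid reference.

    ``df`` is indexed by ``gene_id`` with columns ``chromosome``,
    ``species``, ``biotype`` and the derived boolean ``is_mito``.
    Reporter transgenes carry ``species == "reporter"`` and are excluded
    from the species chromosome sets used for on/off-target
    classification.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"chromosome", "species", "biotype", "is_mito"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"gene table missing columns: {sorted(missing)}")
        dup = self.df.index[self.df.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene_id: {dup[0]!r}")
        per_chrom = self.df.groupby("chromosome", sort=False)["species"].nunique()
        bad = per_chrom[per_chrom > 1]
        if len(bad):
            raise ValidationError(
                f"chromosome {bad.index[0]!r} is assigned to more than one species"
            )

    # -- convenience views -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.df.index

    def chrom_species(self) -> pd.Series:
        """chromosome -> species, one entry per chromosome."""
        return self.df.drop_duplicates("chromosome").set_index("chromosome")["species"]

    def chrom_is_mito(self) -> pd.Series:
        return self.df.drop_duplicates("chromosome").set_index("chromosome")["is_mito"]

    def species_chromosomes(self, species: str) -> list[str]:
        cs = self.chrom_species()
        return list(cs.index[cs == species])

    @property
    def species_labels(self) -> list[str]:
        """Species in order of first appearance, reporters excluded."""
        seen = self.df["species"].drop_duplicates()
        return [s for s in seen if s != REPORTER_SPECIES]

    def reporter_genes(self) -> pd.Index:
        return self.df.index[self.df["species"] == REPORTER_SPECIES]

    def subset(self, genes) -> "GeneTable":
        return GeneTable(self.df.loc[genes])


def read_gene_table(path, mito_names=DEFAULT_MITO_NAMES) -> GeneTable:
    """Read a tab-separated gene annotation table.

    Expects header columns ``gene_id``, ``chromosome``, ``species``,
    ``biotype``.  ``is_mito`` is derived from ``mito_names`` (exact match,
    or match of the suffix after the last underscore, so prefixed hybrid
    names like ``hs_MT`` are recognised).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chromosome", "species", "biotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"gene table {path}: missing columns {missing}")
    df = df.set_index("gene_id")
    df["is_mito"] = [_is_mito_name(c, mito_names) for c in df["chromosome"]]
    return GeneTable(df)


def write_gene_table(gene_table: GeneTable, path) -> None:
    out = gene_table.df[["chromosome", "species", "biotype"]].copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# featureCounts-dialect count matrices
# ---------------------------------------------------------------------------

_FC_META = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]


def _collapse_chr(entry: str, gene_id: str) -> str:
    parts = set(str(entry).split(";"))
    if len(parts) != 1:
        raise ValidationError(
            f"gene {gene_id!r}: Chr entry {entry!r} names more than one chromosome"
        )
    return parts.pop()


def read_counts_featurecounts(path, gene_table: GeneTable) -> pd.DataFrame:
    """Read a featureCounts output table into a genes x samples matrix.

    Comment lines starting with ``#`` are skipped.  Multi-segment ``Chr``
    entries (``"chr1;chr1"``) collapse to the unique chromosome; entries
    naming two distinct chromosomes are rejected because the read cannot
    be assigned to one species.  The matrix is restricted to genes present
    in ``gene_table`` and returned in the file's row order.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _FC_META if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: not a featureCounts table, missing {missing}")
    sample_cols = [c for c in df.columns if c not in _FC_META]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns")
    chroms = [
        _collapse_chr(entry, gid) for entry, gid in zip(df["Chr"], df["Geneid"])
    ]
    counts = df[sample_cols]
    as_float = counts.apply(pd.to_numeric, errors="coerce")
    if as_float.isna().any().any():
        col = as_float.columns[as_float.isna().any()][0]
        raise ValidationError(f"{path}: non-numeric count in sample column {col!r}")
    if not (as_float == as_float.round()).all().all():
        raise ValidationError(f"{path}: non-integer counts")
    if (as_float < 0).any().any():
        raise ValidationError(f"{path}: negative counts")
    mat = as_float.astype(np.int64)
    mat.index = pd.Index(df["Geneid"], name="gene_id")
    keep = mat.index.isin(gene_table.genes)
    mat = mat.loc[keep]
    # cross-check chromosome assignment against the annotation
    ann_chrom = gene_table.df.loc[mat.index, "chromosome"]
    file_chrom = pd.Series(chroms, index=pd.Index(df["Geneid"], name="gene_id"))[keep]
    bad = ann_chrom != file_chrom
    if bad.any():
        g = ann_chrom.index[bad][0]
        raise ValidationError(
            f"{path}: gene {g!r} chromosome {file_chrom[g]!r} disagrees with "
            f"annotation {ann_chrom[g]!r}"
        )
    return mat


def write_counts_featurecounts(counts: pd.DataFrame, gene_table: GeneTable, path) -> None:
    """Write a genes x samples matrix in the featureCounts dialect.

    Start/End/Strand/Length are synthesised placeholders; only Geneid, Chr
    and the sample columns are meaningful on re-read.
    """
    ann = gene_table.df.loc[counts.index]
    out = pd.DataFrame(
        {
            "Geneid": counts.index,
            "Chr": ann["chromosome"].to_numpy(),
            "Start": 1,
            "End": 1000,
            "Strand": "+",
            "Length": 1000,
        }
    )
    for c in counts.columns:
        out[c] = counts[c].to_numpy()
    with open(path, "w") as fh:
        fh.write("# Program:ribotag; simulated featureCounts-dialect table\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# samtools idxstats chromosome-level counts
# ---------------------------------------------------------------------------

def read_idxstats(path) -> pd.Series:
    """Read one sample's idxstats output (chromosome, length, mapped, unmapped).

    The mapped column becomes the chromosome count; the unplaced ``*`` row
    is ignored.  Returns a Series indexed by chromosome.
    """
    rows: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, _length, mapped, _unmapped = parts
            if chrom == "*":
                continue
            try:
                n = int(mapped)
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-integer mapped count {mapped!r}")
            if n < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            rows.append((chrom, n))
    s = pd.Series(dict(rows), dtype=np.int64)
    s.index.name = "chromosome"
    return s


def write_idxstats(chrom_counts: pd.Series, path, lengths=None) -> None:
    with open(path, "w") as fh:
        for chrom, n in chrom_counts.items():
            length = 1000 if lengths is None else lengths[chrom]
            fh.write(f"{chrom}\t{length}\t{int(n)}\t0\n")
        fh.write("*\t0\t0\t0\n")


# ---------------------------------------------------------------------------
# sample sheets and IP/input pairing
# ---------------------------------------------------------------------------

_ROLES = {"input", "ip"}
_ANTIBODIES = {"HA", "V5", "none"}


@dataclass
class SampleSheet:
    """Sample metadata; ``df`` is indexed by sample_id.

    Columns: ``role`` (input|ip), ``antibody`` (HA|V5|none),
    ``on_target_species``, ``input_sample_id``, ``replicate_label`` and
    optionally ``rna_yield_ng``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id {dup[0]!r}")
        for col in ("role", "antibody"):
            if col not in df.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        bad_role = set(df["role"]) - _ROLES
        if bad_role:
            raise ValidationError(f"unknown role {bad_role.pop()!r}")
        bad_ab = set(df["antibody"]) - _ANTIBODIES
        if bad_ab:
            raise ValidationError(f"unknown antibody {bad_ab.pop()!r}")
        for sid, row in df.iterrows():
            if row["role"] == "input":
                if row["antibody"] != "none":
                    raise ValidationError(f"input sample {sid!r} declares an antibody")
                ref = row.get("input_sample_id")
                if isinstance(ref, str) and ref:
                    raise ValidationError(f"input sample {sid!r} references an input")
            else:
                ref = row.get("input_sample_id")
                if not isinstance(ref, str) or not ref:
                    raise ValidationError(f"IP sample {sid!r} lacks input_sample_id")
                if ref not in df.index:
                    raise ValidationError(
                        f"IP sample {sid!r} references unknown input {ref!r}"
                    )
                if df.loc[ref, "role"] != "input":
                    raise ValidationError(
                        f"IP sample {sid!r} references {ref!r}, which is not an input"
                    )

    @property
    def samples(self) -> pd.Index:
        return self.df.index

    def ip_samples(self) -> pd.Index:
        return self.df.index[self.df["role"] == "ip"]


def read_sample_sheet(path) -> SampleSheet:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str}).set_index("sample_id")
    for col in df.columns:
        if df[col].dtype == object or df[col].isna().all():
            df[col] = df[col].astype(object).where(df[col].notna(), "")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    out = sheet.df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def pair_samples(sheet: SampleSheet) -> list[tuple[str, str]]:
    """(ip, input) pairs in sheet order; several IPs may share one input."""
    pairs = []
    for sid, row in sheet.df.iterrows():
        if row["role"] == "ip":
            pairs.append((sid, row["input_sample_id"]))
    return pairs


# ---------------------------------------------------------------------------
# canonical TSV output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV with floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
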