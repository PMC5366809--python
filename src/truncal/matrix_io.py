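"""Binary alteration matrices: reading, writing, VCF ingestion and
perfect-phylogeny (homoplasy) filtering.

The empirical substrate of the whole pipeline is a binary presence/absence
matrix with one row per somatic alteration (mutation, copy-number event,
any inheritable change treated as an abstract id) and one column per
multi-region tumour sample.  On disk it is a TSV/CSV table whose first
column header is the literal ``alteration_id`` and whose remaining headers
are sample names.

False-negative calls (normal contamination, limited depth) make some
characters contradict any single tree -- homoplasy.  For binary characters
with ancestral state 0 the standard criterion is the three-gamete test: two
alterations are incompatible with one tree iff the sample patterns (1,1),
(1,0) and (0,1) all occur.  :func:`filter_homoplasy` greedily removes the
most-conflicted alterations until the matrix is pairwise compatible.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlterationMatrix",
    "ConflictReport",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "vcf_to_matrix",
    "find_conflicts",
    "filter_homoplasy",
]

_INDEX_NAME = "alteration_id"
_SEP = {"tsv": "\t", "csv": ","}


class MatrixFormatError(ValueError):
    """Raised for malformed matrix input (non-binary cells, duplicate ids,
    wrong orientation, empty tables)."""


class AlterationMatrix:
    """Validated binary sample x alteration matrix.

    Rows are alterations, columns are samples, entries are 0/1.  Alterations
    absent from every sample carry no phylogenetic signal and are dropped at
    construction time with a warning.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise MatrixFormatError("matrix must have at least 1 sample and 1 alteration")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate alteration identifiers: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample identifiers: {dups}")
        values = data.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"non-binary entry {values[r, c]!r} at alteration "
                f"{data.index[r]!r}, sample {data.columns[c]!r}"
            )
        data = data.astype(np.int8)
        empty = data.sum(axis=1) == 0
        if empty.any():
            dropped = data.index[empty].tolist()
            warnings.warn(
                f"dropping {len(dropped)} alteration(s) absent from every sample: "
                f"{dropped}",
                stacklevel=2,
            )
            data = data.loc[~empty]
        if data.shape[0] == 0:
            raise MatrixFormatError("matrix has no alteration present in any sample")
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        data.index.name = _INDEX_NAME
        self.data = data

    # -- convenience ------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def alteration_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_alterations(self) -> int:
        return self.data.shape[0]

    def values(self) -> np.ndarray:
        """Presence matrix as a boolean (alterations x samples) array."""
        return self.data.to_numpy(dtype=bool)

    def sample_set(self, sample_id: str) -> set[str]:
        """Set of alteration ids present in one sample."""
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample id {sample_id!r}")
        col = self.data[sample_id]
        return set(col.index[col == 1])

    @classmethod
    def from_sample_sets(
        cls,
        sample_sets: dict[str, set[str]],
        alteration_order: list[str] | None = None,
    ) -> "AlterationMatrix":
        """Build a matrix from a mapping sample id -> set of alteration ids."""
        if alteration_order is None:
            seen: dict[str, None] = {}
            for ids in sample_sets.values():
                for a in sorted(ids):
                    seen.setdefault(a, None)
            alteration_order = list(seen)
        frame = pd.DataFrame(
            {s: [1 if a in ids else 0 for a in alteration_order] for s, ids in sample_sets.items()},
            index=pd.Index(alteration_order, name=_INDEX_NAME),
        )
        return cls(frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AlterationMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return (
            f"AlterationMatrix({self.n_alterations} alterations x "
            f"{self.n_samples} samples)"
        )


def read_matrix(source, dialect: str = "tsv") -> AlterationMatrix:
    """Read a presence/absence table from a path or text stream.

    The first header cell must be the literal ``alteration_id`` (rows =
    alterations, columns = samples); a table in the transposed orientation
    is rejected rather than silently transposed.
    """
    if dialect not in _SEP:
        raise ValueError(f"dialect must be one of {sorted(_SEP)}, got {dialect!r}")
    # header parsed from an unlabelled read so duplicate sample names are
    # caught before pandas mangles them to s1, s1.1, ...
    raw = pd.read_csv(source, sep=_SEP[dialect], dtype=str, header=None)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise MatrixFormatError("empty matrix")
    header = raw.iloc[0].tolist()
    if header[0] != _INDEX_NAME:
        raise MatrixFormatError(
            f"first column header must be {_INDEX_NAME!r} (rows = alterations, "
            f"columns = samples); got {header[0]!r} — is the table transposed?"
        )
    sample_ids = [str(s) for s in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise MatrixFormatError(f"duplicate sample identifiers: {dups}")
    frame = raw.iloc[1:].copy()
    frame.index = frame.iloc[:, 0].astype(str)
    frame.index.name = _INDEX_NAME
    frame = frame.iloc[:, 1:]
    frame.columns = sample_ids
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate alteration identifiers: {dups}")
    for col in frame.columns:
        stripped = frame[col].str.strip()
        ok = stripped.isin(("0", "1"))
        if not ok.all():
            row = frame.index[~ok][0]
            raise MatrixFormatError(
                f"non-binary cell {frame.loc[row, col]!r} at alteration "
                f"{row!r}, sample {col!r}"
            )
        frame[col] = stripped.astype(np.int8)
    return AlterationMatrix(frame)


def write_matrix(matrix: AlterationMatrix, sink, dialect: str = "tsv") -> None:
    """Write a matrix so that :func:`read_matrix` reproduces it exactly."""
    if dialect not in _SEP:
        raise ValueError(f"dialect must be one of {sorted(_SEP)}, got {dialect!r}")
    matrix.data.to_csv(sink, sep=_SEP[dialect], index_label=_INDEX_NAME)


def vcf_to_matrix(vcf_source: str, missing_policy: str = "absent") -> AlterationMatrix:
    """Build an alteration matrix from a multi-sample VCF.

    One alteration per VCF record, id ``CHROM:POS:REF:ALT``; a sample is
    scored present (1) iff its genotype carries at least one alternate
    allele.  Read depth, VAF and FILTER are deliberately ignored:
    binarization thresholds belong upstream of this tool.

    Parameters
    ----------
    vcf_source
        Path to a VCF file (plain text or bgzipped).
    missing_policy
        ``"absent"``: missing genotypes (``./.``) score 0 and are counted in
        a single summary warning.  ``"drop_site"``: a record with any
        missing genotype is excluded.
    """
    import pysam

    if missing_policy not in ("absent", "drop_site"):
        raise ValueError(f"missing_policy must be 'absent' or 'drop_site', got {missing_policy!r}")
    with pysam.VariantFile(str(vcf_source)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise MatrixFormatError("VCF has no sample columns (genotypes required)")
        rows: dict[str, list[int]] = {}
        n_missing = 0
        for rec in vcf:
            alt = ",".join(rec.alts) if rec.alts else "."
            alt_id = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            presence = []
            any_missing = False
            for s in samples:
                gt = rec.samples[s].get("GT")
                alleles = [a for a in (gt or ()) if a is not None]
                if not alleles:
                    any_missing = True
                    presence.append(0)
                else:
                    presence.append(1 if any(a > 0 for a in alleles) else 0)
            if any_missing:
                if missing_policy == "drop_site":
                    continue
                n_missing += 1
            rows[alt_id] = presence
    if n_missing:
        warnings.warn(
            f"{n_missing} record(s) had missing genotypes scored as absent",
            stacklevel=2,
        )
    if not rows:
        raise MatrixFormatError("no VCF records retained")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    frame.index.name = _INDEX_NAME
    return AlterationMatrix(frame)


@dataclass
class ConflictReport:
    """Outcome of the pairwise three-gamete compatibility test.

    ``conflicting_pairs`` lists every unordered alteration pair exhibiting
    all three patterns (1,1), (1,0), (0,1) across samples;
    ``conflicts_per_alteration`` counts, for every alteration in the
    matrix, how many conflicts it participates in.
    """

    conflicting_pairs: list[tuple[str, str]] = field(default_factory=list)
    conflicts_per_alteration: dict[str, int] = field(default_factory=dict)

    @property
    def is_compatible(self) -> bool:
        return not self.conflicting_pairs

    def to_json(self, removed: list[str] | None = None) -> str:
        return json.dumps(
            {
                "conflicting_pairs": [list(p) for p in self.conflicting_pairs],
                "removed": list(removed or []),
            }
        )


def find_conflicts(matrix: AlterationMatrix) -> ConflictReport:
    """Run the three-gamete test on every unordered pair of alterations.

    Binary characters with ancestral (germline) state 0 fit a single tree
    iff no pair shows all three joint patterns (1,1), (1,0), (0,1).  The
    pattern counts are computed as integer matrix products, so the test is
    O(m^2 s) with small constants.
    """
    a = matrix.values().astype(np.int64)
    n11 = a @ a.T
    n10 = a @ (1 - a).T
    conflict = (n11 > 0) & (n10 > 0) & (n10.T > 0)
    ids = matrix.alteration_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = conflict[iu, ju]
    pairs = [(ids[i], ids[j]) for i, j in zip(iu[mask], ju[mask])]
    counts = dict(zip(ids, (conflict.sum(axis=1)).tolist()))
    return ConflictReport(conflicting_pairs=pairs, conflicts_per_alteration=counts)


def filter_homoplasy(matrix: AlterationMatrix) -> tuple[AlterationMatrix, list[str]]:
    """Remove alterations until the matrix is perfect-phylogeny compatible.

    Greedy heuristic: repeatedly delete the alteration involved in the most
    conflicts (ties broken by lexicographically smallest id) and re-test.
    Deterministic, and removes few characters when homoplasy is sparse --
    the situation this models, where a handful of false-negative calls
    contradict an otherwise clean tree.  Exact minimum removal is NP-hard
    and out of scope.

    Returns the filtered matrix and the removed ids in removal order.
    """
    removed: list[str] = []
    current = matrix
    while True:
        report = find_conflicts(current)
        if report.is_compatible:
            return current, removed
        top = max(report.conflicts_per_alteration.values())
        victim = min(
            a for a, c in report.conflicts_per_alteration.items() if c == top
        )
        removed.append(victim)
        frame = current.data.drop(index=victim)
        if frame.shape[0] == 0:
            raise MatrixFormatError("matrix fully conflicted: every alteration removed")
        current = AlterationMatrix(frame)
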