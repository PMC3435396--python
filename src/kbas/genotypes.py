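"""Genotype containers, file readers and SNP prioritization.

Genotypes are encoded by minor-allele count: with A the major and B the
minor allele of a biallelic marker, AA = 0, AB = 1 and BB = 2.  Major and
minor are decided from allele counts pooled over *both* phenotype groups,
so the encoding of a marker is identical for cases and controls and does
not depend on which allele a VCF happens to call REF.  Missing genotypes
are carried as an explicit sentinel (:data:`MISSING`) and are never
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call inside ``GenotypeMatrix.values``.
MISSING: int = -1

#: Functional categories in decreasing priority for representative-SNP
#: selection (non-synonymous coding first, intronic last).
CATEGORY_RANK: tuple[str, ...] = (
    "nonsynonymous_coding",
    "promoter",
    "exon_intron_junction",
    "synonymous_coding",
    "other_exonic",
    "intronic",
)


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates the documented dialect."""


class NotBiallelicError(ValueError):
    """Raised when a marker does not have exactly two alleles."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs grid of encoded genotypes.

    Parameters
    ----------
    subject_ids:
        Unique subject identifiers, one per row.
    snp_ids:
        Unique marker identifiers, one per column.
    values:
        ``int8`` array of shape ``(len(subject_ids), len(snp_ids))`` with
        entries in ``{0, 1, 2, MISSING}``.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = list(self.subject_ids)
        self.snp_ids = list(self.snp_ids)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.subject_ids),
            len(self.snp_ids),
        ):
            raise GenotypeFormatError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        for name, ids in (("subject", self.subject_ids), ("SNP", self.snp_ids)):
            if len(set(ids)) != len(ids):
                raise GenotypeFormatError(f"duplicate {name} IDs")
        ok = np.isin(self.values, (0, 1, 2, MISSING))
        if not ok.all():
            bad = sorted(set(self.values[~ok].tolist()))
            raise GenotypeFormatError(f"invalid genotype values {bad}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``snp_ids`` (in that order)."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise KeyError(f"SNPs absent from matrix: {missing}")
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(self.subject_ids, list(snp_ids), self.values[:, cols])

    def monomorphic_snps(self) -> list[str]:
        """SNPs whose non-missing genotypes are all identical (or all missing).

        Monomorphic markers are retained by every operation; they carry no
        case/control information and contribute exactly 0 to any score.
        """
        out = []
        for j, snp in enumerate(self.snp_ids):
            col = self.values[:, j]
            obs = np.unique(col[col != MISSING])
            if len(obs) <= 1:
                out.append(snp)
        return out


@dataclass
class CohortPair:
    """Two genotype cohorts typed on the same markers (e.g. case/control)."""

    group1: GenotypeMatrix
    group2: GenotypeMatrix
    labels: tuple[str, str] = ("case", "control")

    def __post_init__(self) -> None:
        if self.group1.snp_ids != self.group2.snp_ids:
            raise GenotypeFormatError("cohorts must share the same SNPs in the same order")
        overlap = set(self.group1.subject_ids) & set(self.group2.subject_ids)
        if overlap:
            raise GenotypeFormatError(f"subjects present in both groups: {sorted(overlap)[:5]}")

    @property
    def snp_ids(self) -> list[str]:
        return self.group1.snp_ids

    def subset_snps(self, snp_ids: Sequence[str]) -> "CohortPair":
        return CohortPair(
            self.group1.subset_snps(snp_ids), self.group2.subset_snps(snp_ids), self.labels
        )

    def swapped(self) -> "CohortPair":
        return CohortPair(self.group2, self.group1, (self.labels[1], self.labels[0]))


@dataclass(frozen=True)
class SnpAnnotation:
    """Functional annotation of a SNP relative to one transcript.

    ``position`` is 1-based (dbSNP/VCF convention).
    """

    snp_id: str
    transcript_id: str
    category: str
    position: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_RANK:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORY_RANK}"
            )


def determine_minor_allele(allele_counts: Mapping[str, int]) -> tuple[str, str]:
    """Return ``(major, minor)`` from pooled allele counts.

    The minor allele has the strictly smaller pooled count; on an exact tie
    the lexicographically later allele string is declared minor so the
    result is deterministic.  A monomorphic marker (one count zero) is
    allowed: the observed allele is major.
    """
    if len(allele_counts) != 2:
        raise NotBiallelicError(
            f"expected exactly two alleles, got {sorted(allele_counts)}"
        )
    (a1, c1), (a2, c2) = sorted(allele_counts.items())
    if c1 < 0 or c2 < 0 or (c1 == 0 and c2 == 0):
        raise ValueError("allele counts must be nonnegative with at least one positive")
    if c1 == c2:
        return a1, a2  # tie: lexicographically later allele (a2) is minor
    return (a1, a2) if c1 > c2 else (a2, a1)


def _parse_table(path: str | Path) -> tuple[list[str], list[str], list[list[str]]]:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise GenotypeFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 1:
        raise GenotypeFormatError(f"{path}: missing header")
    snp_ids = header[1:]
    subject_ids, rows = [], []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise GenotypeFormatError(
                f"{path}: row for {cells[0]!r} has {len(cells) - 1} values, "
                f"expected {len(snp_ids)}"
            )
        subject_ids.append(cells[0])
        rows.append(cells[1:])
    return subject_ids, snp_ids, rows


def read_genotype_table(path: str | Path, dialect: str = "numeric") -> GenotypeMatrix:
    """Read a tab-separated genotype table.

    Two dialects are supported.  ``numeric``: cells are ``0``, ``1``, ``2``
    or ``NA``.  ``allele_pair``: cells are two-character allele strings
    (``"AG"``) or ``NN`` for missing; the file is converted to the numeric
    encoding by counting alleles over the whole file and applying
    :func:`determine_minor_allele` per SNP.
    """
    if dialect not in ("numeric", "allele_pair"):
        raise ValueError(f"unknown dialect {dialect!r}")
    subject_ids, snp_ids, rows = _parse_table(path)
    n, m = len(subject_ids), len(snp_ids)
    values = np.full((n, m), MISSING, dtype=np.int8)
    if dialect == "numeric":
        lut = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
        for i, row in enumerate(rows):
            for j, cell in enumerate(row):
                try:
                    values[i, j] = lut[cell]
                except KeyError:
                    raise GenotypeFormatError(
                        f"{path}: invalid numeric genotype {cell!r} "
                        f"(subject {subject_ids[i]}, SNP {snp_ids[j]})"
                    ) from None
    else:
        for j in range(m):
            counts: dict[str, int] = {}
            for row in rows:
                cell = row[j]
                if cell == "NN":
                    continue
                if len(cell) != 2 or not cell.isalpha():
                    raise GenotypeFormatError(
                        f"{path}: invalid allele pair {cell!r} (SNP {snp_ids[j]})"
                    )
                for a in cell:
                    counts[a] = counts.get(a, 0) + 1
            if not counts:
                continue  # SNP entirely missing
            if len(counts) == 1:
                major = next(iter(counts))
                minor = None
            else:
                major, minor = determine_minor_allele(counts)
            for i, row in enumerate(rows):
                cell = row[j]
                if cell == "NN":
                    continue
                values[i, j] = sum(1 for a in cell if a != major)
                if minor is None and any(a != major for a in cell):
                    raise GenotypeFormatError(
                        f"{path}: unexpected allele in {cell!r} at SNP {snp_ids[j]}"
                    )
    return GenotypeMatrix(subject_ids, snp_ids, values)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the numeric TSV dialect (bit-exact round trip with the reader)."""
    lut = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("subject_id\t" + "\t".join(matrix.snp_ids) + "\n")
        for i, sid in enumerate(matrix.subject_ids):
            cells = [lut[int(v)] for v in matrix.values[i]]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_vcf_biallelic(
    path: str | Path, sample_subset: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a minor-allele-count matrix.

    Multiallelic records and indels are skipped (a count is logged).  The
    encoded value of each genotype is the number of copies of the cohort
    minor allele, where minor/major are determined from the allele counts
    pooled over the ingested samples — *not* from REF/ALT orientation.
    ``./.`` and half-calls become :data:`MISSING`.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in samples]
        if missing:
            raise KeyError(f"samples absent from VCF: {missing}")
        keep = [samples.index(s) for s in sample_subset]
        samples = list(sample_subset)
    else:
        keep = list(range(len(samples)))

    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if rec.gt_types is None:
            raise GenotypeFormatError(f"{path}: record without GT field at {rec.POS}")
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        alt_dose = rec.gt_types[keep].astype(np.int8)
        alt_dose[alt_dose == 3] = MISSING
        obs = alt_dose[alt_dose != MISSING]
        alt_count = int(obs.sum())
        ref_count = int(2 * len(obs) - alt_count)
        counts = {rec.REF: ref_count, rec.ALT[0]: alt_count}
        major, _minor = determine_minor_allele(counts)
        col = alt_dose.copy()
        if major == rec.ALT[0]:  # ALT is the major allele: flip the dose
            flip = col != MISSING
            col[flip] = 2 - col[flip]
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        columns.append(col)
    if n_skipped:
        logger.info("read_vcf_biallelic: skipped %d non-biallelic-SNP records", n_skipped)
    values = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, snp_ids, values)


def read_snp_annotations(path: str | Path) -> list[SnpAnnotation]:
    """Read the annotation TSV (columns snp_id, transcript_id, category, position)."""
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["snp_id", "transcript_id", "category", "position"]
        if header != expected:
            raise GenotypeFormatError(f"{path}: header must be {expected}")
        for ln in fh:
            if not ln.strip():
                continue
            snp, tx, cat, pos = ln.rstrip("\n").split("\t")
            out.append(SnpAnnotation(snp, tx, cat, int(pos)))
    return out


def prioritize_representative_snps(
    annotations: Iterable[SnpAnnotation], per_transcript: int = 1
) -> list[str]:
    """Pick up to ``per_transcript`` representative SNPs per transcript.

    SNPs are ranked by functional category (:data:`CATEGORY_RANK`, most
    consequential first); ties within a category break by ascending
    position, then snp_id.  Output order follows first appearance of each
    transcript, deterministic for a given input order.
    """
    if per_transcript < 1:
        raise ValueError("per_transcript must be >= 1")
    rank = {c: r for r, c in enumerate(CATEGORY_RANK)}
    by_tx: dict[str, list[SnpAnnotation]] = {}
    for ann in annotations:
        by_tx.setdefault(ann.transcript_id, []).append(ann)
    chosen: list[str] = []
    seen: set[str] = set()
    for tx_annotations in by_tx.values():
        ordered = sorted(
            tx_annotations, key=lambda a: (rank[a.category], a.position, a.snp_id)
        )
        for ann in ordered[:per_transcript]:
            if ann.snp_id not in seen:
                seen.add(ann.snp_id)
                chosen.append(ann.snp_id)
    return chosen
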