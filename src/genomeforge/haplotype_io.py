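"""Haplotype matrix container and I/O (hapt dialect, phased VCF, padding).

The universal currency of the package is the :class:`HaplotypeMatrix`: a
binary matrix whose rows are phased haplotypes and whose columns are biallelic
SNPs coded 0 (reference) / 1 (alternative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class HaptFormatError(ValueError):
    """Raised when a hapt file violates the whitespace 0/1 dialect."""


class VcfFormatError(ValueError):
    """Raised when a VCF record cannot be interpreted as phased biallelic."""


@dataclass
class HaplotypeMatrix:
    """Binary phased-haplotype matrix.

    Parameters
    ----------
    alleles
        ``(n_haplotypes, n_snps)`` array with entries in {0, 1}.
    positions
        Optional 1-based base-pair coordinate per SNP, strictly increasing.
    labels
        Optional per-row identifiers.
    pad_mask
        Optional boolean array over columns; True marks padding columns that
        carry no data and should be excluded from evaluation statistics.
    """

    alleles: np.ndarray
    positions: np.ndarray | None = None
    labels: list[str] | None = None
    pad_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 1:
            raise ValueError("alleles must be a 2-D matrix with at least one row")
        bad = ~np.isin(self.alleles, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(f"non-binary allele {self.alleles[r, c]} at row {r}, column {c}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (self.n_snps,):
                raise ValueError("positions length must equal n_snps")
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
        if self.labels is not None and len(self.labels) != self.n_haplotypes:
            raise ValueError("labels length must equal n_haplotypes")
        if self.pad_mask is not None:
            self.pad_mask = np.asarray(self.pad_mask, dtype=bool)
            if self.pad_mask.shape != (self.n_snps,):
                raise ValueError("pad_mask length must equal n_snps")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def frequencies(self) -> np.ndarray:
        """Per-column alternative-allele frequency."""
        return self.alleles.mean(axis=0)

    def drop_padding(self) -> "HaplotypeMatrix":
        """Return a copy restricted to non-padding columns."""
        if self.pad_mask is None or not self.pad_mask.any():
            return self
        keep = ~self.pad_mask
        pos = self.positions[keep] if self.positions is not None else None
        return HaplotypeMatrix(self.alleles[:, keep], positions=pos, labels=self.labels)

    def __eq__(self, other: object) -> bool:  # row/column content equality
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        if self.alleles.shape != other.alleles.shape or not np.array_equal(self.alleles, other.alleles):
            return False
        if (self.positions is None) != (other.positions is None):
            return False
        if self.positions is not None and not np.array_equal(self.positions, other.positions):
            return False
        return (self.labels or None) == (other.labels or None)


def read_hapt(path, has_label_columns: bool | None = None) -> HaplotypeMatrix:
    """Read a whitespace-delimited 0/1 haplotype file.

    The dialect optionally carries two leading columns (group label and
    sample id). When ``has_label_columns`` is None, label columns are
    auto-detected from a non-numeric first token.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if tok:
                rows.append(tok)
    if not rows:
        raise HaptFormatError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise HaptFormatError(f"{path}: ragged rows (token counts {sorted(widths)})")
    if has_label_columns is None:
        first = rows[0][0]
        has_label_columns = first not in ("0", "1")
    labels = None
    if has_label_columns:
        labels = [" ".join(r[:2]) for r in rows]
        rows = [r[2:] for r in rows]
    n_cols = len(rows[0])
    data = np.empty((len(rows), n_cols), dtype=np.int8)
    for i, r in enumerate(rows):
        for j, tok in enumerate(r):
            if tok == "0":
                data[i, j] = 0
            elif tok == "1":
                data[i, j] = 1
            else:
                raise HaptFormatError(f"{path}: non-binary allele token {tok!r} at row {i}, column {j}")
    return HaplotypeMatrix(data, labels=labels)


def write_hapt(matrix: HaplotypeMatrix, path) -> None:
    """Write a haplotype matrix in the hapt dialect (labels first if present)."""
    with open(path, "w") as fh:
        for i in range(matrix.n_haplotypes):
            row = " ".join(str(int(v)) for v in matrix.alleles[i])
            if matrix.labels is not None:
                fh.write(f"{matrix.labels[i]} {row}\n")
            else:
                fh.write(row + "\n")


def read_phased_vcf(path, region: str | None = None) -> HaplotypeMatrix:
    """Read phased GT fields from a VCF into a haplotype matrix.

    Each diploid sample contributes two rows (left haplotype of the ``|``
    separator first). Multiallelic records and records with missing genotypes
    are skipped and counted in the log; an unphased record raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    positions: list[int] = []
    n_skipped = 0
    records = vcf(region) if region else vcf
    for rec in records:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy+1); last col = phased flag
        alleles = gts[:, :2]
        if (alleles < 0).any():
            n_skipped += 1
            continue
        if not gts[:, 2].all():
            raise VcfFormatError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        cols.append(alleles.astype(np.int8).reshape(-1))
        positions.append(rec.POS)
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d multiallelic/missing records", n_skipped)
    if not cols:
        raise VcfFormatError(f"{path}: no usable biallelic phased records")
    alleles = np.stack(cols, axis=1)
    labels = [f"{s}_{h}" for s in samples for h in (1, 2)]
    return HaplotypeMatrix(alleles, positions=np.array(positions), labels=labels)


def pad_to_pow2m1(matrix: HaplotypeMatrix, pad_value: int = 0) -> HaplotypeMatrix:
    """Pad columns up to the smallest 2**n - 1 >= n_snps with ``pad_value``.

    Convolutional architectures in this package scale along lengths of the
    form 2**n - 1; shorter inputs are right-padded with a constant allele and
    the padded columns are recorded in ``pad_mask`` so that evaluation
    statistics can exclude them. Idempotent.
    """
    if pad_value not in (0, 1):
        raise ValueError("pad_value must be 0 or 1")
    n = matrix.n_snps
    target = 1
    while target < n:
        target = 2 * target + 1
    if target == n:
        if matrix.pad_mask is None:
            return HaplotypeMatrix(
                matrix.alleles, positions=matrix.positions, labels=matrix.labels,
                pad_mask=np.zeros(n, dtype=bool),
            )
        return matrix
    pad = np.full((matrix.n_haplotypes, target - n), pad_value, dtype=np.int8)
    mask = np.zeros(target, dtype=bool)
    if matrix.pad_mask is not None:
        mask[:n] = matrix.pad_mask
    mask[n:] = True
    # positions are dropped: padded columns have no genomic coordinate
    if matrix.positions is not None:
        warnings.warn("pad_to_pow2m1 drops positions (padding has no coordinates)")
    return HaplotypeMatrix(
        np.concatenate([matrix.alleles, pad], axis=1), labels=matrix.labels, pad_mask=mask,
    )
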