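"""Allele-B-fraction preparation for segmentation.

Tumor BAF profiles are only informative at SNPs that are heterozygous in
the patient's germline: homozygous SNPs sit at 0 or 1 regardless of the
tumor's copy-number state.  The pipeline therefore (i) genotypes the
matched *normal* sample with a naive threshold rule, (ii) keeps only
heterozygous SNPs in the tumor signal, and (iii) mirrors the result around
0.5 (mBAF, max(b, 1-b)) so that allelic imbalance becomes a one-sided
piecewise-constant signal segmentable exactly like copy number.

Genotyping a tumor sample directly is unsupported: aberrations break the
bi-allelic cluster assumption, so a matched normal is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import MarkerMap, PairingTable, SignalMatrix

__all__ = [
    "GenotypeVector",
    "naive_genotype",
    "filter_heterozygous",
    "mirror_baf",
    "prepare_baf",
]

GENOTYPES = ("AA", "AB", "BB")


@dataclass(frozen=True)
class GenotypeVector:
    """Per-marker germline genotype calls (AA/AB/BB) from a normal sample."""

    marker_id: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=str))
        object.__setattr__(self, "calls", np.asarray(self.calls, dtype="U2"))
        if len(self.marker_id) != len(self.calls):
            raise ValueError("one call per marker required")
        bad = ~np.isin(self.calls, GENOTYPES)
        if bad.any():
            raise ValueError(f"invalid genotype call {self.calls[bad][0]!r}")

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def is_het(self) -> np.ndarray:
        return self.calls == "AB"


def naive_genotype(normal_baf, marker_id=None, *, thresholds=(1.0 / 3.0, 2.0 / 3.0)
                   ) -> GenotypeVector:
    """Threshold genotyping of a normal sample's BAF.

    AA if b < thresholds[0], AB if thresholds[0] <= b <= thresholds[1]
    (boundaries inclusive for AB), BB if b > thresholds[1].  Assumes
    bi-allelic SNPs; apply to normal (non-tumor) samples only.
    """
    b = np.asarray(normal_baf, dtype=np.float64)
    if (b < 0).any() or (b > 1).any():
        bad = b[(b < 0) | (b > 1)][0]
        raise ValueError(f"BAF value {bad} outside [0, 1]")
    lo, hi = thresholds
    if not (0 < lo < hi < 1):
        raise ValueError("thresholds must satisfy 0 < lo < hi < 1")
    calls = np.full(len(b), "AB", dtype="U2")
    calls[b < lo] = "AA"
    calls[b > hi] = "BB"
    if marker_id is None:
        marker_id = np.arange(len(b)).astype(str)
    return GenotypeVector(marker_id=np.asarray(marker_id), calls=calls)


def filter_heterozygous(tumor_baf, genotypes: GenotypeVector, markers: MarkerMap):
    """Restrict a tumor BAF series to germline-heterozygous SNPs.

    Returns (reduced series, retained MarkerMap) preserving genomic order.
    """
    b = np.asarray(tumor_baf, dtype=np.float64)
    if len(b) != len(genotypes) or len(markers) != len(genotypes):
        raise ValueError(
            f"marker sets differ: tumor has {len(b)}, genotypes {len(genotypes)}, "
            f"map {len(markers)}"
        )
    if not np.array_equal(markers.marker_id, genotypes.marker_id):
        raise ValueError("tumor markers and genotype markers do not match")
    het = genotypes.is_het
    if not het.any():
        warnings.warn("no heterozygous SNPs retained")
    return b[het], markers.subset(het)


def mirror_baf(b) -> np.ndarray:
    """Mirror BAF around 0.5: max(b, 1-b), mapping [0,1] onto [0.5, 1].

    At heterozygous SNPs the mirrored signal behaves like a one-sided
    copy-number-like profile: 0.5 for allelic balance, rising toward 1
    under loss of heterozygosity.  Idempotent and symmetric in b <-> 1-b.
    """
    b = np.asarray(b, dtype=np.float64)
    return 0.5 + np.abs(b - 0.5)


def prepare_baf(signal: SignalMatrix, tumor: str, normal: str | None = None, *,
                pairing: PairingTable | None = None,
                thresholds=(1.0 / 3.0, 2.0 / 3.0)) -> SignalMatrix:
    """Produce the mirrored heterozygous-SNP BAF profile of one tumor.

    The matched normal is located through ``pairing`` unless given
    explicitly; a tumor without a matched normal is a hard error because
    naive genotyping is only valid on normal samples.  The returned
    single-column SignalMatrix feeds segmentation unchanged.
    """
    if signal.signal_kind != "allele_b_fraction":
        raise ValueError("prepare_baf requires an allele_b_fraction signal")
    if normal is None:
        if pairing is None:
            raise ValueError(
                f"tumor sample {tumor!r} has no matched normal: allele-B-fraction "
                "segmentation requires matched normal-tumor pairs"
            )
        normal = pairing.normal_of(tumor)
    genotypes = naive_genotype(
        signal.column(normal), signal.markers.marker_id, thresholds=thresholds
    )
    reduced, markers = filter_heterozygous(signal.column(tumor), genotypes,
                                           signal.markers)
    mirrored = mirror_baf(reduced)
    return SignalMatrix(markers, [str(tumor)], mirrored[:, None],
                        "allele_b_fraction", validate=False)
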