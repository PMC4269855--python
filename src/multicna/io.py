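"""Core data containers and delimited-text I/O.

The pipeline operates on dense per-marker signal matrices (rows = genomic
markers, columns = samples) of normalized total copy number or allele B
fraction, together with an optional patient response vector and a matched
normal/tumor pairing table.  All on-disk formats are plain TSV/CSV so that
users can bring their own normalized data.

Coordinate conventions: marker positions are 1-based points; emitted segment
intervals are 0-based half-open (BED convention) for genome-browser
interoperability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIGNAL_KINDS",
    "KARYOTYPE_ORDER",
    "MarkerMap",
    "SignalMatrix",
    "ResponseVector",
    "PairingTable",
    "read_signal_matrix",
    "write_signal_matrix",
    "read_segment_table",
    "write_segment_table",
    "read_response",
    "write_response",
    "read_pairing",
    "write_pairing",
    "split_by_chromosome",
    "concatenate_chromosomes",
    "anscombe_transform",
    "normalize_chromosome",
]

SIGNAL_KINDS = ("copy_number", "allele_b_fraction", "log2ratio")

KARYOTYPE_ORDER = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: r for r, c in enumerate(KARYOTYPE_ORDER)}

SEGMENT_COLUMNS = ["chromosome", "start", "end", "sample", "mean", "n_probes"]


def normalize_chromosome(label: object) -> str:
    """Normalize a chromosome label: strip a leading 'chr' prefix."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def chromosome_rank(chrom: str):
    """Sort key putting chromosomes in karyotype order 1..22, X, Y."""
    return (_CHROM_RANK.get(chrom, len(KARYOTYPE_ORDER)), chrom)


class MarkerMap:
    """Genomic coordinates and identifiers of the P markers.

    The shared row index for every signal matrix: ``marker_id`` (unique),
    ``chromosome`` ('1'..'22', 'X', 'Y', normalized), ``position`` (1-based
    base pairs, strictly increasing within each chromosome).  Rows are stored
    in karyotype order.
    """

    __slots__ = ("marker_id", "chromosome", "position")

    def __init__(self, marker_id, chromosome, position, *, validate: bool = True):
        self.marker_id = np.asarray(marker_id, dtype=str)
        self.chromosome = np.asarray(
            [normalize_chromosome(c) for c in np.asarray(chromosome)], dtype=str
        )
        self.position = np.asarray(position, dtype=np.int64)
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.marker_id)
        if len(self.chromosome) != n or len(self.position) != n:
            raise ValueError("marker_id, chromosome and position must have equal length")
        if n == 0:
            return
        ids, counts = np.unique(self.marker_id, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][:5].tolist()
            raise ValueError(f"duplicate marker IDs: {dup}")
        if (self.position <= 0).any():
            raise ValueError("marker positions must be positive (1-based)")
        ranks = np.array([chromosome_rank(c)[0] for c in self.chromosome])
        lex = [chromosome_rank(c)[1] for c in self.chromosome]
        for i in range(1, n):
            same = self.chromosome[i] == self.chromosome[i - 1]
            if same:
                if self.position[i] <= self.position[i - 1]:
                    raise ValueError(
                        f"positions not strictly increasing within chromosome "
                        f"{self.chromosome[i]} at row {i}"
                    )
            elif (ranks[i], lex[i]) < (ranks[i - 1], lex[i - 1]):
                raise ValueError("chromosomes not in karyotype order; use from_frame to sort")
        # chromosome blocks must be contiguous
        block_labels = [self.chromosome[0]]
        for c in self.chromosome[1:]:
            if c != block_labels[-1]:
                block_labels.append(c)
        if len(set(block_labels)) != len(block_labels):
            raise ValueError("chromosome blocks are not contiguous")

    def __len__(self) -> int:
        return len(self.marker_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        return (
            np.array_equal(self.marker_id, other.marker_id)
            and np.array_equal(self.chromosome, other.chromosome)
            and np.array_equal(self.position, other.position)
        )

    def __repr__(self) -> str:
        return f"MarkerMap(P={len(self)}, chromosomes={list(self.chromosomes)})"

    @property
    def chromosomes(self) -> tuple:
        """Unique chromosome labels in karyotype order."""
        _, idx = np.unique(self.chromosome, return_index=True)
        return tuple(self.chromosome[np.sort(idx)])

    def chromosome_slices(self) -> dict:
        """Map chromosome label -> row slice of its contiguous block."""
        out = {}
        for c in self.chromosomes:
            w = np.flatnonzero(self.chromosome == c)
            out[c] = slice(int(w[0]), int(w[-1]) + 1)
        return out

    def subset(self, index) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[index], self.chromosome[index], self.position[index]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position": self.position,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, sort: bool = True) -> "MarkerMap":
        df = df.copy()
        df["chromosome"] = df["chromosome"].map(normalize_chromosome)
        if sort:
            key = df["chromosome"].map(lambda c: chromosome_rank(c)[0])
            df = (
                df.assign(_rank=key)
                .sort_values(["_rank", "chromosome", "position"], kind="mergesort")
                .drop(columns="_rank")
            )
        return cls(
            df["marker_id"].to_numpy(),
            df["chromosome"].to_numpy(),
            df["position"].to_numpy(),
        )


class SignalMatrix:
    """P x I matrix of a normalized genomic signal.

    ``values[p, i]`` is the signal of marker p in sample i.  ``signal_kind``
    is one of 'copy_number' (values >= 0), 'allele_b_fraction' (values in
    [0, 1], clipped on construction with a warning) or 'log2ratio'.
    """

    __slots__ = ("markers", "samples", "values", "signal_kind")

    def __init__(self, markers: MarkerMap, samples: Sequence[str], values,
                 signal_kind: str, *, validate: bool = True):
        self.markers = markers
        self.samples = list(map(str, samples))
        self.values = np.array(values, dtype=np.float64, copy=True)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.signal_kind = signal_kind
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")
        P, I = self.values.shape
        if P != len(self.markers):
            raise ValueError(f"values has {P} rows but MarkerMap has {len(self.markers)}")
        if I != len(self.samples):
            raise ValueError(f"values has {I} columns but {len(self.samples)} sample IDs")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if not np.isfinite(self.values).all():
            p, i = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at marker {self.markers.marker_id[p]!r}, "
                f"sample {self.samples[i]!r}; missing values are not permitted"
            )
        if self.signal_kind == "allele_b_fraction":
            lo, hi = self.values.min(initial=0.0), self.values.max(initial=1.0)
            if lo < 0.0 or hi > 1.0:
                warnings.warn(
                    "allele B fractions outside [0, 1] clipped "
                    f"(range was [{lo:.4g}, {hi:.4g}])"
                )
                np.clip(self.values, 0.0, 1.0, out=self.values)
        elif self.signal_kind == "copy_number":
            if (self.values < 0).any():
                p, i = np.argwhere(self.values < 0)[0]
                raise ValueError(
                    f"negative copy number at marker {self.markers.marker_id[p]!r}, "
                    f"sample {self.samples[i]!r}"
                )

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:
        return (
            f"SignalMatrix(kind={self.signal_kind!r}, P={self.n_markers}, "
            f"I={self.n_samples})"
        )

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(str(sample))
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def column(self, sample: str) -> np.ndarray:
        """Signal of one sample across all markers (copy)."""
        return self.values[:, self.sample_index(sample)].copy()

    def subset_markers(self, index) -> "SignalMatrix":
        return SignalMatrix(
            self.markers.subset(index), self.samples, self.values[index],
            self.signal_kind, validate=False,
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.markers.to_frame()
        for j, s in enumerate(self.samples):
            df[s] = self.values[:, j]
        return df


@dataclass(frozen=True)
class ResponseVector:
    """Patient-level outcome: one value per sample.

    ``response_kind`` is 'continuous' or 'binary' (values in {0, 1}).
    """

    samples: tuple
    values: np.ndarray
    response_kind: str = "continuous"

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(map(str, self.samples)))
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if len(self.samples) != len(vals):
            raise ValueError("one response value per sample required")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs in response")
        if not np.isfinite(vals).all():
            raise ValueError("non-finite response values")
        if self.response_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        if self.response_kind == "binary" and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("binary response values must be in {0, 1}")

    def reindex(self, samples: Iterable[str]) -> np.ndarray:
        """Values aligned to the given sample order."""
        lookup = dict(zip(self.samples, self.values))
        try:
            return np.array([lookup[str(s)] for s in samples])
        except KeyError as e:
            raise ValueError(f"sample {e.args[0]!r} missing from response") from None


@dataclass(frozen=True)
class PairingTable:
    """Matched normal/tumor sample pairs (rows of normal_id, tumor_id)."""

    pairs: tuple

    def __post_init__(self):
        pairs = tuple((str(n), str(t)) for n, t in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        tumors = [t for _, t in pairs]
        if len(set(tumors)) != len(tumors):
            raise ValueError("a tumor sample appears more than once in the pairing table")

    def normal_of(self, tumor: str) -> str:
        for n, t in self.pairs:
            if t == str(tumor):
                return n
        raise KeyError(
            f"tumor sample {tumor!r} has no matched normal; allele-B-fraction "
            "analysis requires matched normal-tumor pairs"
        )

    def validate_against(self, signal: SignalMatrix) -> None:
        known = set(signal.samples)
        for n, t in self.pairs:
            for s in (n, t):
                if s not in known:
                    raise ValueError(f"pairing sample {s!r} not present in signal matrix")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path, "r") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_signal_matrix(path, signal_kind: str) -> SignalMatrix:
    """Read a delimited signal matrix.

    The file must be tab- or comma-delimited with a header; the first three
    columns are marker_id, chromosome, position, remaining columns are
    samples.  Rows are sorted to karyotype order (with a warning if the file
    was unsorted); duplicate marker IDs or non-numeric cells are hard errors.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str},
                     float_precision="round_trip")
    if df.shape[1] < 4:
        raise ValueError(
            f"{path}: need marker_id, chromosome, position plus >=1 sample column"
        )
    df.columns = ["marker_id", "chromosome", "position"] + list(df.columns[3:])
    sample_cols = list(df.columns[3:])
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at marker "
                f"{df['marker_id'].iloc[row]!r}, column {col!r}"
            )
        df[col] = numeric
    df["position"] = pd.to_numeric(df["position"], errors="raise").astype(np.int64)
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)

    rank = df["chromosome"].map(lambda c: chromosome_rank(c)[0])
    sorted_df = (
        df.assign(_rank=rank)
        .sort_values(["_rank", "chromosome", "position"], kind="mergesort")
        .drop(columns="_rank")
    )
    if not sorted_df.index.equals(df.index):
        warnings.warn(f"{path}: rows were not in genomic order; sorted")
    sorted_df = sorted_df.reset_index(drop=True)

    markers = MarkerMap(
        sorted_df["marker_id"].to_numpy(),
        sorted_df["chromosome"].to_numpy(),
        sorted_df["position"].to_numpy(),
    )
    values = sorted_df[sample_cols].to_numpy(dtype=np.float64)
    return SignalMatrix(markers, sample_cols, values, signal_kind)


def _float17(v: float) -> str:
    # 17 significant digits: parses back to the identical float64
    return format(v, ".17g")


def write_signal_matrix(signal: SignalMatrix, path) -> None:
    """Write a signal matrix as the TSV layout `read_signal_matrix` accepts.

    Floats are written with 17 significant digits so a read-back is
    bit-exact.
    """
    signal.to_frame().to_csv(path, sep="\t", index=False, float_format=_float17)


def write_segment_table(segments: pd.DataFrame, path) -> None:
    """Write a segment table as BED-like TSV.

    Columns: chromosome, start (0-based half-open), end, sample, mean,
    n_probes and, when present, label and posterior-probability columns.
    Floats carry 17 significant digits so read-back is exact.
    """
    cols = [c for c in SEGMENT_COLUMNS if c in segments.columns]
    missing = set(SEGMENT_COLUMNS) - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns {sorted(missing)}")
    extra = [c for c in segments.columns if c not in cols]
    segments[cols + extra].to_csv(path, sep="\t", index=False, float_format=_float17)


def read_segment_table(path) -> pd.DataFrame:
    """Read a segment table written by :func:`write_segment_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "sample": str},
                     float_precision="round_trip")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: segment table missing columns {sorted(missing)}")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    for col in ("start", "end", "n_probes"):
        df[col] = df[col].astype(np.int64)
    return df


def read_response(path, response_kind: str = "continuous") -> ResponseVector:
    """Read a two-column (sample_id, value) TSV/CSV response file."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id, value")
    return ResponseVector(
        df.iloc[:, 0].tolist(),
        pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(),
        response_kind,
    )


def write_response(response: ResponseVector, path) -> None:
    pd.DataFrame({"sample_id": response.samples, "value": response.values}).to_csv(
        path, sep="\t", index=False
    )


def read_pairing(path) -> PairingTable:
    """Read a two-column (normal_id, tumor_id) TSV/CSV pairing file."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns normal_id, tumor_id")
    return PairingTable(tuple(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_pairing(pairing: PairingTable, path) -> None:
    pd.DataFrame(pairing.pairs, columns=["normal_id", "tumor_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Signal utilities
# ---------------------------------------------------------------------------

def split_by_chromosome(signal: SignalMatrix) -> list:
    """Split into per-chromosome matrices, in karyotype order.

    Concatenating the outputs reproduces the input exactly.
    """
    out = []
    for c, sl in signal.markers.chromosome_slices().items():
        out.append(signal.subset_markers(sl))
    return out


def concatenate_chromosomes(parts: Sequence[SignalMatrix]) -> SignalMatrix:
    """Inverse of :func:`split_by_chromosome`."""
    if not parts:
        raise ValueError("nothing to concatenate")
    samples = parts[0].samples
    kind = parts[0].signal_kind
    for p in parts[1:]:
        if p.samples != samples or p.signal_kind != kind:
            raise ValueError("parts disagree on samples or signal kind")
    markers = MarkerMap(
        np.concatenate([p.markers.marker_id for p in parts]),
        np.concatenate([p.markers.chromosome for p in parts]),
        np.concatenate([p.markers.position for p in parts]),
    )
    values = np.vstack([p.values for p in parts])
    return SignalMatrix(markers, samples, values, kind, validate=False)


def anscombe_transform(counts) -> np.ndarray:
    """Variance-stabilizing transform for count data: 2*sqrt(x + 3/8).

    For Poisson inputs with a large mean the output variance is
    approximately 1, making count profiles (e.g. sequencing coverage)
    suitable for the Gaussian segmentation model.
    """
    x = np.asarray(counts, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("anscombe_transform requires nonnegative counts")
    return 2.0 * np.sqrt(x + 0.375)
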