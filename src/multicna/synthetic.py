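"""Synthetic multi-patient cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
piecewise-constant Gaussian copy-number profiles shared (with a carrier
fraction) across patients, bi-allelic SNP genotypes with banded allele B
fractions, healthy-cell dilution through a cellularity parameter, and a
patient response that is linear (or logistic) in the marker values.  It
does not simulate probe-level intensities, GC waves or batch effects.

Randomness flows from a single seed through named substreams, so adding
one output never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import MarkerMap, PairingTable, ResponseVector, SignalMatrix

__all__ = [
    "CNVRegion",
    "CohortSpec",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "default_validation_suite",
]

_BAF_BANDS = {"AA": (0.03, 0.02), "AB": (0.5, 0.04), "BB": (0.97, 0.02)}


@dataclass(frozen=True)
class CNVRegion:
    """A shared copy-number variant: a run of markers with altered copies.

    ``start`` is the 0-based index of the first marker *within its
    chromosome block*; ``width`` the number of markers; ``copies`` the
    carrier state (1 = loss, 3 = gain); ``carrier_fraction`` the expected
    share of patients carrying it.
    """

    chromosome: str
    start: int
    width: int
    copies: int
    carrier_fraction: float = 1.0

    def __post_init__(self):
        if self.width < 1 or self.start < 0:
            raise ValueError("region must have start >= 0 and width >= 1")
        if self.copies not in (1, 2, 3):
            raise ValueError("copies must be 1, 2 or 3")
        if not (0.0 <= self.carrier_fraction <= 1.0):
            raise ValueError("carrier fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a simulated cohort.

    markers_per_chrom maps chromosome label -> marker count; marker
    positions are laid out every 1000 bp.  causal_markers are global row
    indices whose values drive the response with causal_effects
    coefficients (linear model plus Gaussian noise of sd
    response_noise_sd, or a logistic model for binary cohorts).
    """

    name: str
    n_patients: int
    markers_per_chrom: dict
    regions: tuple = ()
    cn_noise_sd: float = 0.25
    baf_noise_sd: float = 0.04
    cellularity: float = 1.0
    causal_markers: tuple = ()
    causal_effects: tuple = ()
    response_noise_sd: float = 0.5
    response_kind: str = "continuous"
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if not (0.0 < self.cellularity <= 1.0):
            raise ValueError("cellularity must be in (0, 1]")
        if len(self.causal_markers) != len(self.causal_effects):
            raise ValueError("one effect per causal marker required")
        sizes = self.markers_per_chrom
        for r in self.regions:
            if r.chromosome not in sizes:
                raise ValueError(f"region on unknown chromosome {r.chromosome!r}")
            if r.start + r.width > sizes[r.chromosome]:
                raise ValueError(
                    f"region {r} exceeds chromosome {r.chromosome!r} "
                    f"({sizes[r.chromosome]} markers)"
                )

    @property
    def n_markers(self) -> int:
        return int(sum(self.markers_per_chrom.values()))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: latent states, genotypes, causal markers."""

    states: np.ndarray            # (P, I) true copies per marker per patient
    genotypes: np.ndarray         # (P, I) germline AA/AB/BB
    causal_markers: np.ndarray    # global row indices
    causal_effects: np.ndarray

    def breakpoints(self, markers: MarkerMap, patient: int) -> dict:
        """Per-chromosome 1-based last-index breakpoints of the true states."""
        out = {}
        for chrom, sl in markers.chromosome_slices().items():
            s = self.states[sl, patient]
            change = np.flatnonzero(np.diff(s) != 0) + 1
            out[chrom] = np.concatenate((change, [len(s)])).astype(np.int64)
        return out


@dataclass(frozen=True)
class SimulatedCohort:
    spec: CohortSpec
    cn: SignalMatrix               # tumor copy number, samples S01..S<I>
    baf: SignalMatrix              # tumor + matched normal BAF columns
    pairing: PairingTable
    response: ResponseVector
    truth: GroundTruth


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


def _marker_map(spec: CohortSpec) -> MarkerMap:
    ids, chroms, pos = [], [], []
    for chrom, n in spec.markers_per_chrom.items():
        ids.extend(f"m{chrom}_{i + 1:06d}" for i in range(n))
        chroms.extend([chrom] * n)
        pos.extend(range(1000, 1000 * (n + 1), 1000))
    return MarkerMap(np.array(ids), np.array(chroms), np.array(pos))


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate one cohort: CN + BAF matrices, pairing, response, truth.

    Tumor copy number is the cellularity-mixed latent state plus Gaussian
    noise, floored at 0.  Normal BAF follows genotype bands (AA ~ N(0.03,
    0.02), AB ~ N(0.5, 0.04), BB ~ N(0.97, 0.02), clipped); tumor BAF
    reflects the regional state (losses push heterozygous SNPs toward
    0/1, gains toward 1/3 / 2/3) mixed with diploid signal according to
    cellularity.  The response is linear (or logistic) in the observed
    marker values at the causal rows.  Bitwise reproducible from the seed.
    """
    markers = _marker_map(spec)
    P, I = spec.n_markers, spec.n_patients
    slices = markers.chromosome_slices()

    # latent copy states
    states = np.full((P, I), 2, dtype=np.int8)
    rng_car = _rng(spec.seed, "carriers")
    for r in spec.regions:
        carriers = rng_car.random(I) < r.carrier_fraction
        sl = slices[r.chromosome]
        rows = slice(sl.start + r.start, sl.start + r.start + r.width)
        states[rows, carriers] = r.copies

    c = spec.cellularity
    cn_clean = c * states + (1.0 - c) * 2.0
    rng_cn = _rng(spec.seed, "cn_noise")
    cn_values = np.maximum(cn_clean + rng_cn.normal(0.0, spec.cn_noise_sd, (P, I)), 0.0)

    tumor_ids = [f"S{i + 1:02d}" for i in range(I)]
    normal_ids = [f"{t}_N" for t in tumor_ids]
    cn = SignalMatrix(markers, tumor_ids, cn_values, "copy_number", validate=False)

    # germline genotypes: shared per-marker allele frequency, HW proportions
    rng_gt = _rng(spec.seed, "genotypes")
    freq = rng_gt.uniform(0.05, 0.95, P)
    u = rng_gt.random((P, I))
    p_aa = (1.0 - freq) ** 2
    p_ab = 2.0 * freq * (1.0 - freq)
    genotypes = np.full((P, I), "AB", dtype="U2")
    genotypes[u < p_aa[:, None]] = "AA"
    genotypes[u > (p_aa + p_ab)[:, None]] = "BB"

    rng_baf = _rng(spec.seed, "baf")
    normal_baf = np.empty((P, I))
    for g, (mu, sd) in _BAF_BANDS.items():
        mask = genotypes == g
        normal_baf[mask] = mu + rng_baf.normal(0.0, sd, int(mask.sum()))
    np.clip(normal_baf, 0.0, 1.0, out=normal_baf)

    # tumor allele fractions by state; which parental allele is hit is
    # drawn once per (region, patient)
    b_germ = np.where(genotypes == "AA", 0.0, np.where(genotypes == "BB", 1.0, 0.5))
    b_tumor = b_germ.copy()
    rng_side = _rng(spec.seed, "loh_side")
    for r in spec.regions:
        if r.copies == 2:
            continue
        sl = slices[r.chromosome]
        rows = slice(sl.start + r.start, sl.start + r.start + r.width)
        affected = states[rows.start] == r.copies  # carriers of this region
        b_lost = rng_side.random(I) < 0.5          # True: B allele hit
        for i in np.flatnonzero(affected):
            het = genotypes[rows, i] == "AB"
            if r.copies == 1:                      # LOH: one allele lost
                b_tumor[rows, i] = np.where(
                    het, 0.0 if b_lost[i] else 1.0, b_germ[rows, i]
                )
            else:                                  # gain: one allele duplicated
                b_tumor[rows, i] = np.where(
                    het, (1.0 / 3.0) if b_lost[i] else (2.0 / 3.0), b_germ[rows, i]
                )
    # cellularity mixing on the allele scale, weighted by copy numbers
    tot = c * states + (1.0 - c) * 2.0
    b_mixed = (c * states * b_tumor + (1.0 - c) * 2.0 * b_germ) / tot
    tumor_baf = np.clip(
        b_mixed + rng_baf.normal(0.0, spec.baf_noise_sd, (P, I)), 0.0, 1.0
    )

    baf = SignalMatrix(
        markers, tumor_ids + normal_ids,
        np.hstack([tumor_baf, normal_baf]), "allele_b_fraction", validate=False,
    )
    pairing = PairingTable(tuple(zip(normal_ids, tumor_ids)))

    # response
    rng_resp = _rng(spec.seed, "response")
    causal = np.asarray(spec.causal_markers, dtype=int)
    effects = np.asarray(spec.causal_effects, dtype=np.float64)
    if len(causal):
        Xc = cn_values[causal].T                   # (I, n_causal)
        eta = (Xc - Xc.mean(axis=0)) @ effects
    else:
        eta = np.zeros(I)
    if spec.response_kind == "binary":
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = (rng_resp.random(I) < prob).astype(float)
    else:
        y = eta + rng_resp.normal(0.0, spec.response_noise_sd, I)
    response = ResponseVector(tumor_ids, y, spec.response_kind)

    truth = GroundTruth(
        states=states, genotypes=genotypes, causal_markers=causal,
        causal_effects=effects,
    )
    return SimulatedCohort(spec=spec, cn=cn, baf=baf, pairing=pairing,
                           response=response, truth=truth)


def default_validation_suite() -> list:
    """The five fixed cohort specifications used by the validation checks.

    1. segmentation-recovery: 200 profiles of 1000 markers with four true
       segments (states 2/1/3/2 copies, boundaries after markers 217, 504
       and 789); noise sd 1/3 so the smallest jump is 3 standard
       deviations.
    2. pure-noise: 100 flat diploid profiles with unit noise (no true
       breakpoints).
    3. calling: 20 profiles carrying one loss and one gain region of >= 20
       probes each; noise sd 0.2 on the copy-number scale (about 0.15 on
       the log2-ratio scale at the diploid level).
    4. linear-selection: 100 patients x 1000 markers, five single-marker
       causal CNVs (carrier fraction 0.5, 3 copies, effect 1 each),
       response noise sd 0.5, plus broader non-causal decoy regions.
    5. logistic-selection: 200 patients x 500 markers, three single-marker
       causal CNVs with logistic coefficients +2/-2/+2.
    """
    segmentation = CohortSpec(
        name="segmentation-recovery",
        n_patients=200,
        markers_per_chrom={"1": 1000},
        regions=(
            CNVRegion("1", 217, 287, 1, 1.0),   # markers 218..504
            CNVRegion("1", 504, 285, 3, 1.0),   # markers 505..789
        ),
        cn_noise_sd=1.0 / 3.0,
        seed=11,
    )
    noise = CohortSpec(
        name="pure-noise",
        n_patients=100,
        markers_per_chrom={"1": 1000},
        cn_noise_sd=1.0,
        seed=12,
    )
    calling = CohortSpec(
        name="calling",
        n_patients=20,
        markers_per_chrom={"1": 600, "2": 400},
        regions=(
            CNVRegion("1", 100, 120, 1, 1.0),
            CNVRegion("1", 400, 100, 3, 1.0),
            CNVRegion("2", 50, 80, 1, 1.0),
            CNVRegion("2", 250, 60, 3, 1.0),
        ),
        cn_noise_sd=0.2,
        seed=13,
    )
    linear = CohortSpec(
        name="linear-selection",
        n_patients=100,
        markers_per_chrom={"1": 500, "2": 500},
        regions=(
            CNVRegion("1", 60, 1, 3, 0.5),
            CNVRegion("1", 240, 1, 3, 0.5),
            CNVRegion("1", 420, 1, 3, 0.5),
            CNVRegion("2", 100, 1, 3, 0.5),
            CNVRegion("2", 350, 1, 3, 0.5),
            # broader non-causal decoys
            CNVRegion("1", 130, 30, 1, 0.3),
            CNVRegion("2", 200, 30, 3, 0.3),
        ),
        cn_noise_sd=0.25,
        causal_markers=(60, 240, 420, 600, 850),
        causal_effects=(1.0, 1.0, 1.0, 1.0, 1.0),
        response_noise_sd=0.5,
        seed=14,
    )
    logistic = CohortSpec(
        name="logistic-selection",
        n_patients=200,
        markers_per_chrom={"1": 250, "2": 250},
        regions=(
            CNVRegion("1", 40, 1, 3, 0.5),
            CNVRegion("1", 180, 1, 3, 0.5),
            CNVRegion("2", 120, 1, 3, 0.5),
            CNVRegion("2", 60, 25, 1, 0.3),
        ),
        cn_noise_sd=0.25,
        causal_markers=(40, 180, 370),
        causal_effects=(2.0, -2.0, 2.0),
        response_kind="binary",
        seed=15,
    )
    return [segmentation, noise, calling, linear, logistic]
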