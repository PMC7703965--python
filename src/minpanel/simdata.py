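"""Synthetic clonal germplasm collections with known ground truth.

The generator emulates the structure of a fingerprinted clonal collection
genotyped on a small biallelic panel: unrelated founder genotypes drawn
marker-wise from Hardy-Weinberg proportions; clone groups (the same
genotype sampled under a shared replicate label, as happens with declared
replicates, synonyms and sports); rare somatic "sport" mutations within
clones; triploid-like accessions whose heterozygosity is inflated; and
observation noise in the form of miscalls, no-calls and swapped replicate
labels.  Every observed-vs-true discrepancy is logged, so downstream
estimators can be checked against the truth.

Markers are independent (no linkage disequilibrium), as the markers of a
well-designed fingerprinting panel are chosen to be.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ParameterError
from .types import (
    HET,
    HOM_X,
    HOM_Y,
    MISSING,
    GenotypeMatrix,
    MarkerInfo,
    SampleInfo,
)

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("A", "T"), ("C", "G")]
_N_CHROMOSOMES = 17  # apple-sized genome; labels cycle chr01..chr17


@dataclass
class SimConfig:
    """Parameters of one simulated collection.

    Defaults emulate a national-collection fingerprinting run: a few
    hundred distinct genotypes typed on a 21-marker panel selected for
    high minor allele frequency, most varieties sampled once, a minority
    with replicates, ~12% triploid-like accessions, a few percent of
    no-calls and sub-percent miscalls.

    ``clone_group_sizes`` maps group size to probability (normalized).
    ``het_inflation`` is the probability that a homozygous founder call
    becomes heterozygous in a triploid-like founder — a phenomenological
    stand-in for the extra allele dose.  ``mislabel_rate`` is the fraction
    of replicate-labelled samples whose label is reassigned to another
    variety.
    """

    n_founders: int = 300
    n_markers: int = 21
    maf_range: tuple[float, float] = (0.2, 0.5)
    clone_group_sizes: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.75, 2: 0.15, 3: 0.07, 4: 0.03}
    )
    sport_mutation_rate: float = 0.0005
    triploid_fraction: float = 0.12
    het_inflation: float = 0.35
    miscall_rate: float = 0.005
    missing_rate: float = 0.035
    mislabel_rate: float = 0.0
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if self.n_founders < 2:
            out.append("n_founders must be >= 2")
        if self.n_markers < 1:
            out.append("n_markers must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            out.append("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in (
            "sport_mutation_rate",
            "triploid_fraction",
            "het_inflation",
            "miscall_rate",
            "missing_rate",
            "mislabel_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                out.append(f"{name} must be in [0, 1], got {v}")
        if not self.clone_group_sizes:
            out.append("clone_group_sizes must be non-empty")
        elif any(s < 1 for s in self.clone_group_sizes):
            out.append("clone group sizes must be >= 1")
        elif any(p < 0 for p in self.clone_group_sizes.values()) or not any(
            p > 0 for p in self.clone_group_sizes.values()
        ):
            out.append("clone_group_sizes probabilities must be non-negative, not all zero")
        return out


@dataclass
class SimTruth:
    """Ground truth accompanying an observed matrix.

    ``true_genotypes`` includes sport mutations (they are real biology);
    ``injected_errors`` and ``injected_missing`` log every observation
    noise event; ``mislabeled`` lists samples whose replicate label was
    reassigned away from their genotype's variety.
    """

    true_genotypes: GenotypeMatrix
    clone_membership: dict[str, int]
    injected_errors: list[tuple[str, str, int, int]]
    injected_missing: list[tuple[str, str]]
    mislabeled: list[str]
    sport_mutations: list[tuple[str, str, int, int]] = field(default_factory=list)
    triploid_founders: list[int] = field(default_factory=list)


def _draw_founders(
    rng: np.random.Generator, n: int, m: int, maf_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)
    u = rng.random((n, m))
    p_hom_x = (1 - mafs) ** 2
    p_het = 2 * mafs * (1 - mafs)
    geno = np.full((n, m), HOM_Y, dtype=np.int8)
    geno[u < p_hom_x + p_het] = HET
    geno[u < p_hom_x] = HOM_X
    return geno, mafs


def inject_errors(
    matrix: GenotypeMatrix,
    miscall_rate: float,
    missing_rate: float,
    seed: int,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overlay miscalls and no-calls on a matrix, logging every change.

    Each called cell independently flips to a uniformly chosen different
    called state with probability ``miscall_rate``, then becomes a no-call
    with probability ``missing_rate``.  A cell that flips and then drops
    out is logged only as missing — the observable discrepancy is the
    no-call.  Returns the noisy matrix and a :class:`SimTruth` whose
    ``true_genotypes`` is the input.
    """
    for name, v in (("miscall_rate", miscall_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    called = calls >= 0

    flip = called & (rng.random(calls.shape) < miscall_rate)
    # uniform among the two other called states
    offset = rng.integers(1, 3, size=calls.shape)
    calls[flip] = (calls[flip] + offset[flip]) % 3

    drop = called & (rng.random(calls.shape) < missing_rate)
    calls[drop] = MISSING

    sample_ids = matrix.sample_ids
    marker_ids = matrix.marker_ids
    errors: list[tuple[str, str, int, int]] = []
    for i, j in np.argwhere(flip & ~drop):
        errors.append(
            (sample_ids[i], marker_ids[j], int(matrix.calls[i, j]), int(calls[i, j]))
        )
    missing: list[tuple[str, str]] = [
        (sample_ids[i], marker_ids[j]) for i, j in np.argwhere(drop)
    ]
    observed = GenotypeMatrix(
        samples=list(matrix.samples), markers=list(matrix.markers), calls=calls
    )
    truth = SimTruth(
        true_genotypes=matrix,
        clone_membership={},
        injected_errors=errors,
        injected_missing=missing,
        mislabeled=[],
    )
    return observed, truth


def simulate_collection(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate an observed genotype matrix plus its ground truth.

    Fully reproducible from ``config.seed``; with all noise rates at zero
    the observed matrix equals the true one exactly.
    """
    bad = config.violations()
    if bad:
        raise ParameterError("invalid SimConfig: " + "; ".join(bad))
    rng = np.random.default_rng(config.seed)

    m = config.n_markers
    founders, _ = _draw_founders(rng, config.n_founders, m, config.maf_range)

    # triploid-like founders get extra heterozygosity (dose effect emulation)
    triploid = rng.random(config.n_founders) < config.triploid_fraction
    if config.het_inflation > 0:
        hom = founders != HET
        boost = hom & triploid[:, None] & (
            rng.random(founders.shape) < config.het_inflation
        )
        founders = founders.copy()
        founders[boost] = HET

    sizes_keys = sorted(config.clone_group_sizes)
    probs = np.array([config.clone_group_sizes[k] for k in sizes_keys], dtype=float)
    probs /= probs.sum()
    group_sizes = rng.choice(sizes_keys, size=config.n_founders, p=probs)

    markers = _make_markers(rng, m)
    samples: list[SampleInfo] = []
    rows: list[np.ndarray] = []
    clone_membership: dict[str, int] = {}
    sport_log: list[tuple[str, str, int, int]] = []
    counter = 0
    for f in range(config.n_founders):
        ploidy = 3 if triploid[f] else 2
        for _ in range(int(group_sizes[f])):
            counter += 1
            sid = f"S{counter:05d}"
            profile = founders[f].copy()
            if config.sport_mutation_rate > 0:
                mut = rng.random(m) < config.sport_mutation_rate
                if mut.any():
                    offset = rng.integers(1, 3, size=m)
                    for j in np.nonzero(mut)[0]:
                        old = int(profile[j])
                        profile[j] = (profile[j] + offset[j]) % 3
                        sport_log.append((sid, markers[j].marker_id, old, int(profile[j])))
            samples.append(
                SampleInfo(
                    sample_id=sid,
                    variety_name=f"V{f:04d}",
                    replicate_label=f"V{f:04d}",
                    reported_ploidy=ploidy,
                )
            )
            rows.append(profile)
            clone_membership[sid] = f

    true_matrix = GenotypeMatrix(
        samples=samples, markers=markers, calls=np.stack(rows)
    )

    noise_seed = int(rng.integers(0, 2**31 - 1))
    observed, noise = inject_errors(
        true_matrix, config.miscall_rate, config.missing_rate, noise_seed
    )

    # label swaps: reassign some replicate-labelled samples to other varieties
    mislabeled: list[str] = []
    if config.mislabel_rate > 0:
        eligible = [
            i
            for i, s in enumerate(samples)
            if group_sizes[clone_membership[s.sample_id]] >= 2
        ]
        k = int(round(config.mislabel_rate * len(eligible)))
        if k > 0:
            picks = rng.choice(len(eligible), size=min(k, len(eligible)), replace=False)
            new_samples = list(observed.samples)
            for p in picks:
                i = eligible[int(p)]
                own = clone_membership[samples[i].sample_id]
                other = int(rng.integers(0, config.n_founders - 1))
                if other >= own:
                    other += 1
                old = new_samples[i]
                new_samples[i] = SampleInfo(
                    sample_id=old.sample_id,
                    variety_name=old.variety_name,
                    replicate_label=f"V{other:04d}",
                    reported_ploidy=old.reported_ploidy,
                )
                mislabeled.append(old.sample_id)
            observed = observed.with_samples(new_samples)

    truth = SimTruth(
        true_genotypes=true_matrix,
        clone_membership=clone_membership,
        injected_errors=noise.injected_errors,
        injected_missing=noise.injected_missing,
        mislabeled=mislabeled,
        sport_mutations=sport_log,
        triploid_founders=[int(f) for f in np.nonzero(triploid)[0]],
    )
    return observed, truth


def _make_markers(rng: np.random.Generator, m: int) -> list[MarkerInfo]:
    out = []
    for j in range(m):
        x, y = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
        out.append(
            MarkerInfo(
                marker_id=f"M{j + 1:04d}",
                allele_x=x,
                allele_y=y,
                chromosome=f"chr{(j % _N_CHROMOSOMES) + 1:02d}",
            )
        )
    return out


__all__ = ["SimConfig", "SimTruth", "simulate_collection", "inject_errors"]
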