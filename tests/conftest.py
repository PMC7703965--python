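"""Shared fixtures and matrix-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from minpanel.types import GenotypeMatrix, MarkerInfo, SampleInfo


def make_matrix(
    rows: list[list[int]],
    marker_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    chromosomes: list[str] | None = None,
    alleles: tuple[str, str] = ("A", "G"),
) -> GenotypeMatrix:
    """Build a GenotypeMatrix straight from call codes.

    codes: 0 = hom-X, 1 = het, 2 = hom-Y, -1 = missing.
    """
    calls = np.asarray(rows, dtype=np.int8)
    n, m = calls.shape
    marker_ids = marker_ids or [f"M{j + 1:02d}" for j in range(m)]
    sample_ids = sample_ids or [f"S{i + 1:02d}" for i in range(n)]
    markers = [
        MarkerInfo(
            marker_id=mid,
            allele_x=alleles[0],
            allele_y=alleles[1],
            chromosome=chromosomes[j] if chromosomes else None,
        )
        for j, mid in enumerate(marker_ids)
    ]
    samples = [SampleInfo(sample_id=sid) for sid in sample_ids]
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


@pytest.fixture
def small_matrix() -> GenotypeMatrix:
    """4 samples x 3 markers with one clone pair and one no-call."""
    return make_matrix(
        [
            [0, 1, 2],
            [0, 1, 2],  # clone of sample 1
            [2, 1, 0],
            [1, -1, 0],
        ]
    )
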