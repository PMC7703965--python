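"""Core data containers for biallelic genotype tables.

A genotype call at a biallelic SNP is one of four states: homozygous for
the marker's X allele, heterozygous, homozygous for the Y allele, or a
no-call.  Calls are stored as small integer codes in a dense
samples x markers array; the nucleotide letters live on the marker, not
on the call, so a whole matrix is a single ``int8`` array plus two
metadata lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

# Call-state codes.  MISSING is negative so "called" is simply ``code >= 0``.
HOM_X: int = 0
HET: int = 1
HOM_Y: int = 2
MISSING: int = -1

CALLED_STATES: tuple[int, int, int] = (HOM_X, HET, HOM_Y)

STATE_NAMES: dict[int, str] = {
    HOM_X: "HOM_X",
    HET: "HET",
    HOM_Y: "HOM_Y",
    MISSING: "MISSING",
}


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one biallelic SNP assay.

    ``allele_x``/``allele_y`` give the two nucleotides the assay reports;
    ``allele_y`` may be ``None`` for a marker observed as monomorphic with
    no declared second allele.  ``primer_sequences`` optionally carries the
    two allele-specific forward primers and the common reverse primer of a
    KASP assay.
    """

    marker_id: str
    allele_x: str
    allele_y: str | None = None
    chromosome: str | None = None
    primer_sequences: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        if self.allele_y is not None and self.allele_x == self.allele_y:
            raise ValidationError(
                f"marker {self.marker_id!r}: allele_x and allele_y must differ"
            )

    @property
    def alleles(self) -> tuple[str, str | None]:
        return (self.allele_x, self.allele_y)

    def render(self, code: int, missing_token: str = "NA") -> str:
        """Render an integer call code as a two-letter genotype string."""
        if code == MISSING:
            return missing_token
        x, y = self.allele_x, self.allele_y
        if code == HOM_X:
            return x + x
        if y is None:
            raise ValidationError(
                f"marker {self.marker_id!r} has no second allele; "
                f"cannot render state {STATE_NAMES.get(code, code)}"
            )
        if code == HET:
            return x + y
        if code == HOM_Y:
            return y + y
        raise ValidationError(f"unknown call code {code!r}")


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sampled accession.

    ``replicate_label`` is the grouping key for declared biological
    replicates (a shared variety name or an external registry code);
    ``reported_ploidy`` is curator-reported and is metadata only — the
    stored calls stay diploid-style regardless.
    """

    sample_id: str
    variety_name: str | None = None
    replicate_label: str | None = None
    reported_ploidy: int | None = None

    def __post_init__(self) -> None:
        if self.reported_ploidy is not None and self.reported_ploidy not in (2, 3, 4):
            raise ValidationError(
                f"sample {self.sample_id!r}: reported_ploidy must be 2, 3 or 4, "
                f"got {self.reported_ploidy!r}"
            )


@dataclass
class GenotypeMatrix:
    """Dense samples x markers table of genotype calls.

    ``calls`` is an ``int8`` array of shape ``(len(samples), len(markers))``
    holding the codes ``HOM_X``/``HET``/``HOM_Y``/``MISSING``.
    """

    samples: list[SampleInfo]
    markers: list[MarkerInfo]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        valid = np.isin(self.calls, (HOM_X, HET, HOM_Y, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValidationError(
                f"invalid call code {self.calls[tuple(bad)]} at "
                f"sample {self.samples[bad[0]].sample_id!r}, "
                f"marker {self.markers[bad[1]].marker_id!r}"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample IDs")
        mids = [m.marker_id for m in self.markers]
        if len(set(mids)) != len(mids):
            raise ValidationError("duplicate marker IDs")

    # -- basic views ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def profile(self, sample: int | str) -> np.ndarray:
        """One sample's call vector across all markers."""
        if isinstance(sample, str):
            sample = self.sample_ids.index(sample)
        return self.calls[sample]

    def marker_column(self, marker: int | str) -> np.ndarray:
        if isinstance(marker, str):
            marker = self.marker_ids.index(marker)
        return self.calls[:, marker]

    # -- subsetting -----------------------------------------------------

    def subset_samples(self, which: Iterable[int] | Iterable[str]) -> "GenotypeMatrix":
        idx = self._resolve(which, self.sample_ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            markers=list(self.markers),
            calls=self.calls[idx, :].copy(),
        )

    def subset_markers(self, which: Iterable[int] | Iterable[str]) -> "GenotypeMatrix":
        idx = self._resolve(which, self.marker_ids)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )

    @staticmethod
    def _resolve(which: Iterable, ids: Sequence[str]) -> list[int]:
        pos = {sid: i for i, sid in enumerate(ids)}
        out: list[int] = []
        for w in which:
            if isinstance(w, str):
                if w not in pos:
                    raise ValidationError(f"unknown ID {w!r}")
                out.append(pos[w])
            else:
                out.append(int(w))
        return out

    def with_samples(self, samples: list[SampleInfo]) -> "GenotypeMatrix":
        """Same calls, replacement sample metadata (e.g. edited labels)."""
        if len(samples) != self.n_samples:
            raise ValidationError("sample metadata length mismatch")
        return GenotypeMatrix(samples=samples, markers=list(self.markers), calls=self.calls)

    # -- text rendering -------------------------------------------------

    def to_frame(self, missing_token: str = "NA") -> pd.DataFrame:
        """Two-letter genotype strings, sample IDs as index, marker IDs as columns."""
        cols = {}
        for j, m in enumerate(self.markers):
            cols[m.marker_id] = [m.render(c, missing_token) for c in self.calls[:, j]]
        return pd.DataFrame(cols, index=pd.Index(self.sample_ids, name="sample_id"))

    def replicate_labels(self) -> dict[str, str]:
        """Mapping sample_id -> replicate_label for samples that carry one."""
        return {
            s.sample_id: s.replicate_label
            for s in self.samples
            if s.replicate_label is not None
        }


def is_called(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of non-missing calls."""
    return np.asarray(codes) >= 0


__all__ = [
    "HOM_X",
    "HET",
    "HOM_Y",
    "MISSING",
    "CALLED_STATES",
    "STATE_NAMES",
    "MarkerInfo",
    "SampleInfo",
    "GenotypeMatrix",
    "is_called",
]
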