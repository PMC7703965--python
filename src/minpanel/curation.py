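"""Profile grouping, replicate merging, cross-platform concordance and
heterozygosity for curated genotype tables.

A "SNP profile" is the vector of genotype calls for one sample across the
panel.  Identical profiles flag clones, sports or synonyms; a no-call that
recurs across every member of a clonal group is a candidate null allele
(primer-site variation) rather than a random assay failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyInputError,
    ParameterError,
    StrandAmbiguityError,
    UndefinedResultError,
    ValidationError,
)
from .types import HET, HOM_X, HOM_Y, MISSING, GenotypeMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# Profile grouping
# ---------------------------------------------------------------------------


@dataclass
class ProfileGroup:
    """Samples sharing one SNP profile.

    ``representative_profile`` is the shared call vector (for merged or
    compatibility groups, the per-marker modal called state).
    ``systematic_null_markers`` lists markers missing in *every* member —
    for groups of two or more, a reproducible no-call shared by a clonal
    group points at a null allele.
    """

    member_sample_ids: list[str]
    representative_profile: np.ndarray
    systematic_null_markers: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_sample_ids)


def _modal_profile(calls: np.ndarray) -> np.ndarray:
    """Per-marker modal non-missing state; MISSING where nothing is called."""
    n, m = calls.shape
    out = np.full(m, MISSING, dtype=np.int8)
    for j in range(m):
        col = calls[:, j]
        col = col[col >= 0]
        if col.size:
            vals, counts = np.unique(col, return_counts=True)
            out[j] = vals[np.argmax(counts)]  # ties -> lowest state code
    return out


def find_systematic_nulls(group: ProfileGroup, matrix: GenotypeMatrix) -> list[str]:
    """Markers at which every member of the group has a no-call.

    For a singleton group the notion is vacuous (one missing call is not
    evidence of anything systematic): returns an empty list with a warning.
    """
    if group.size < 2:
        warnings.warn(
            "systematic-null detection needs a group of >= 2 samples; "
            "returning empty list",
            stacklevel=2,
        )
        return []
    sub = matrix.subset_samples(group.member_sample_ids)
    all_missing = (sub.calls == MISSING).all(axis=0)
    return [mid for mid, m in zip(matrix.marker_ids, all_missing) if m]


def group_identical_profiles(
    matrix: GenotypeMatrix, missing_mode: str = "strict"
) -> list[ProfileGroup]:
    """Partition samples into groups of equal SNP profiles.

    ``missing_mode="strict"``: two profiles are equal iff every marker state
    matches, a no-call matching only a no-call.  ``"compatible"``: a no-call
    matches anything and groups are the transitive closure of pairwise
    compatibility — this can over-merge (A~B and B~C do not imply A and C
    agree), so a warning is emitted.

    Groups are returned in order of first member appearance; their members
    partition the samples.
    """
    if matrix.n_samples == 0:
        raise EmptyInputError("cannot group an empty matrix")
    if missing_mode not in ("strict", "compatible"):
        raise ParameterError(f"unknown missing_mode {missing_mode!r}")

    calls = matrix.calls
    sample_ids = matrix.sample_ids

    if missing_mode == "strict":
        seen: dict[tuple, int] = {}
        members: list[list[int]] = []
        for i in range(matrix.n_samples):
            key = tuple(calls[i].tolist())
            if key in seen:
                members[seen[key]].append(i)
            else:
                seen[key] = len(members)
                members.append([i])
    else:
        warnings.warn(
            "compatible-mode grouping merges across no-calls transitively "
            "and can unite samples that would differ if fully called",
            stacklevel=2,
        )
        parent = list(range(matrix.n_samples))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(matrix.n_samples):
            for k in range(i + 1, matrix.n_samples):
                a, b = calls[i], calls[k]
                conflict = (a >= 0) & (b >= 0) & (a != b)
                if not conflict.any():
                    ra, rb = find(i), find(k)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        roots: dict[int, int] = {}
        members = []
        for i in range(matrix.n_samples):
            r = find(i)
            if r in roots:
                members[roots[r]].append(i)
            else:
                roots[r] = len(members)
                members.append([i])

    groups = []
    for idx in members:
        rep = (
            calls[idx[0]].copy()
            if missing_mode == "strict"
            else _modal_profile(calls[idx])
        )
        g = ProfileGroup(
            member_sample_ids=[sample_ids[i] for i in idx],
            representative_profile=rep,
        )
        if g.size >= 2:
            sub = calls[idx]
            nulls = (sub == MISSING).all(axis=0)
            g.systematic_null_markers = [
                mid for mid, m in zip(matrix.marker_ids, nulls) if m
            ]
        groups.append(g)
    return groups


@dataclass
class MergeRecord:
    label: str
    group_a_members: list[str]
    group_b_members: list[str]
    diff_count: int


def merge_replicate_groups(
    groups: Sequence[ProfileGroup],
    replicate_labels: Mapping[str, str],
    max_diff: int = 1,
    matrix: GenotypeMatrix | None = None,
) -> tuple[list[ProfileGroup], list[MergeRecord]]:
    """Merge profile groups that are declared replicates and nearly identical.

    Two groups merge iff at least one member of each carries the same
    ``replicate_label`` and their representative profiles differ at no more
    than ``max_diff`` markers (positions where either side is a no-call are
    not counted as differences).  This formalizes the manual adjustment of
    miscall-split replicate groups: merging is gated on a declared label,
    never attempted between unlabelled look-alikes.

    When ``matrix`` is given, merged representatives and systematic-null
    lists are recomputed from the underlying calls.
    """
    if max_diff < 0:
        raise ParameterError("max_diff must be >= 0")
    unknown = set(replicate_labels) - {
        sid for g in groups for sid in g.member_sample_ids
    }
    if unknown:
        warnings.warn(
            f"replicate labels for unknown samples ignored: {sorted(unknown)[:5]}",
            stacklevel=2,
        )

    label_to_groups: dict[str, list[int]] = {}
    for gi, g in enumerate(groups):
        for sid in g.member_sample_ids:
            lab = replicate_labels.get(sid)
            if lab is not None:
                label_to_groups.setdefault(lab, []).append(gi)

    parent = list(range(len(groups)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    log: list[MergeRecord] = []
    for lab in sorted(label_to_groups):
        idxs = sorted(set(label_to_groups[lab]))
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                a, b = groups[idxs[ai]], groups[idxs[bi]]
                pa, pb = a.representative_profile, b.representative_profile
                both = (pa >= 0) & (pb >= 0)
                diff = int(np.count_nonzero(both & (pa != pb)))
                if diff <= max_diff:
                    ra, rb = find(idxs[ai]), find(idxs[bi])
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
                        log.append(
                            MergeRecord(
                                label=lab,
                                group_a_members=list(a.member_sample_ids),
                                group_b_members=list(b.member_sample_ids),
                                diff_count=diff,
                            )
                        )

    clusters: dict[int, list[int]] = {}
    for gi in range(len(groups)):
        clusters.setdefault(find(gi), []).append(gi)

    merged: list[ProfileGroup] = []
    for root in sorted(clusters):
        idxs = clusters[root]
        if len(idxs) == 1:
            merged.append(groups[idxs[0]])
            continue
        member_ids = [sid for gi in idxs for sid in groups[gi].member_sample_ids]
        if matrix is not None:
            sub = matrix.subset_samples(member_ids)
            rep = _modal_profile(sub.calls)
            nulls = (sub.calls == MISSING).all(axis=0)
            null_ids = [mid for mid, m in zip(matrix.marker_ids, nulls) if m]
        else:
            reps = np.stack([groups[gi].representative_profile for gi in idxs])
            rep = _modal_profile(reps)
            null_ids = []
        merged.append(
            ProfileGroup(
                member_sample_ids=member_ids,
                representative_profile=rep,
                systematic_null_markers=null_ids,
            )
        )
    return merged, log


# ---------------------------------------------------------------------------
# Cross-platform concordance
# ---------------------------------------------------------------------------


def harmonize_strand(
    calls: np.ndarray,
    source_alleles: tuple[str, str],
    target_alleles: tuple[str, str],
    mapping: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Re-express calls scored on one DNA strand in another platform's alleles.

    When one platform reports the opposite strand, each allele maps to its
    base complement; homozygotes become the complement homozygote and
    heterozygotes stay heterozygous.  For palindromic SNPs (A/T, C/G) the
    complement pair equals the original pair and the correspondence cannot
    be inferred — an explicit ``mapping`` (source letter -> target letter)
    is required.

    Returns a new call-code array expressed in ``target_alleles``
    orientation; no-calls pass through unchanged.
    """
    sx, sy = (a.upper() for a in source_alleles)
    tx, ty = (a.upper() for a in target_alleles)
    if mapping is None:
        if {sx, sy} == {_COMPLEMENT[sx], _COMPLEMENT[sy]}:
            raise StrandAmbiguityError(
                f"palindromic SNP {sx}/{sy}: strand correspondence is ambiguous; "
                f"supply an explicit mapping"
            )
        mapping = {sx: _COMPLEMENT[sx], sy: _COMPLEMENT[sy]}
    mx, my = mapping[sx], mapping[sy]
    if {mx, my} != {tx, ty}:
        raise ValidationError(
            f"mapped alleles {mx}/{my} do not match target pair {tx}/{ty}"
        )
    out = np.asarray(calls, dtype=np.int8).copy()
    if mx == ty:  # orientation swapped: hom-X <-> hom-Y
        out[np.asarray(calls) == HOM_X] = HOM_Y
        out[np.asarray(calls) == HOM_Y] = HOM_X
    return out


@dataclass
class ConcordanceReport:
    """Per-marker and overall agreement between two call tables.

    ``per_marker`` columns: compared, agree, het_to_hom, hom_to_het,
    other_disagree.  Pairs where either platform gave a no-call are not
    compared.  ``het_to_hom`` counts cells heterozygous on the first
    platform but homozygous on the second; ``other_disagree`` counts
    opposite-homozygote disagreements.
    """

    per_marker: pd.DataFrame
    overall_percent: float

    @property
    def compared(self) -> int:
        return int(self.per_marker["compared"].sum())

    @property
    def agree(self) -> int:
        return int(self.per_marker["agree"].sum())


def concordance_stats(
    calls_a: GenotypeMatrix, calls_b: GenotypeMatrix
) -> ConcordanceReport:
    """Agreement statistics between two platforms on the same samples/markers.

    Both matrices must cover identical sample and marker ID sets (after any
    strand harmonization); ``calls_b`` is reordered to match ``calls_a``.
    """
    if set(calls_a.sample_ids) != set(calls_b.sample_ids) or set(
        calls_a.marker_ids
    ) != set(calls_b.marker_ids):
        missing_s = sorted(set(calls_a.sample_ids) ^ set(calls_b.sample_ids))
        missing_m = sorted(set(calls_a.marker_ids) ^ set(calls_b.marker_ids))
        raise AlignmentError(
            f"matrices do not align; unmatched samples {missing_s[:5]}, "
            f"unmatched markers {missing_m[:5]}"
        )
    b = calls_b.subset_samples(calls_a.sample_ids).subset_markers(calls_a.marker_ids)
    a_calls, b_calls = calls_a.calls, b.calls

    both = (a_calls >= 0) & (b_calls >= 0)
    agree = both & (a_calls == b_calls)
    het_to_hom = both & (a_calls == HET) & ((b_calls == HOM_X) | (b_calls == HOM_Y))
    hom_to_het = both & (b_calls == HET) & ((a_calls == HOM_X) | (a_calls == HOM_Y))
    other = both & ~agree & ~het_to_hom & ~hom_to_het

    per_marker = pd.DataFrame(
        {
            "compared": both.sum(axis=0),
            "agree": agree.sum(axis=0),
            "het_to_hom": het_to_hom.sum(axis=0),
            "hom_to_het": hom_to_het.sum(axis=0),
            "other_disagree": other.sum(axis=0),
        },
        index=pd.Index(calls_a.marker_ids, name="marker_id"),
    )
    total = int(both.sum())
    overall = 100.0 * int(agree.sum()) / total if total else float("nan")
    return ConcordanceReport(per_marker=per_marker, overall_percent=overall)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------


def sample_heterozygosity(profile: np.ndarray) -> float:
    """Fraction of heterozygous calls among genotyped (non-missing) loci."""
    p = np.asarray(profile)
    called = p[p >= 0]
    if called.size == 0:
        raise UndefinedResultError("all calls missing; heterozygosity undefined")
    return float(np.count_nonzero(called == HET)) / called.size


def matrix_heterozygosity(matrix: GenotypeMatrix) -> pd.Series:
    """Per-sample heterozygosity; NaN for samples with no called loci."""
    called = (matrix.calls >= 0).sum(axis=1)
    het = (matrix.calls == HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.Series(vals, index=pd.Index(matrix.sample_ids, name="sample_id"))


@dataclass
class PloidySummary:
    """Heterozygosity summarized by reported ploidy.

    ``groups``: per-ploidy n and mean heterozygosity.  ``top_tail`` /
    ``bottom_tail``: ploidy composition of the ``tail_k`` samples with the
    highest / lowest heterozygosity — a cheap screen for unreported
    triploids, which carry elevated heterozygosity.
    """

    groups: pd.DataFrame
    top_tail: pd.Series
    bottom_tail: pd.Series
    tail_k: int


def summarize_by_ploidy(
    het_values: Mapping[str, float] | pd.Series,
    ploidy: Mapping[str, int],
    tail_k: int = 200,
) -> PloidySummary:
    """Group mean heterozygosity by ploidy and profile the extreme tails.

    Samples without a ploidy label are summarized under ``"unknown"``.
    ``tail_k`` is clipped to the number of samples.
    """
    het = pd.Series(dict(het_values)) if not isinstance(het_values, pd.Series) else het_values
    het = het.dropna()
    if het.empty:
        raise EmptyInputError("no heterozygosity values to summarize")
    labels = het.index.map(lambda s: str(ploidy.get(s, "unknown")))
    df = pd.DataFrame({"het": het.values, "ploidy": labels.values}, index=het.index)
    groups = (
        df.groupby("ploidy")["het"].agg(n="size", mean_heterozygosity="mean")
    )
    k = min(tail_k, len(df))
    ordered = df.sort_values("het", kind="stable")
    bottom = ordered.head(k)["ploidy"].value_counts()
    top = ordered.tail(k)["ploidy"].value_counts()
    return PloidySummary(groups=groups, top_tail=top, bottom_tail=bottom, tail_k=k)


__all__ = [
    "ProfileGroup",
    "MergeRecord",
    "ConcordanceReport",
    "PloidySummary",
    "group_identical_profiles",
    "merge_replicate_groups",
    "find_systematic_nulls",
    "harmonize_strand",
    "concordance_stats",
    "sample_heterozygosity",
    "matrix_heterozygosity",
    "summarize_by_ploidy",
]
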