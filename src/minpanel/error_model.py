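"""Replicate-based estimation of SNP-calling error rates.

Declared replicates of a clonal variety should have identical SNP
profiles, so any difference between replicates is evidence of a calling
error (which member bore the error cannot be determined).  For a pair of
replicates the error rate is the number of differing markers divided by
the total number of calls made over both samples (42 for two complete
21-marker profiles).  For three or more replicates, the per-marker
majority state is taken as correct and each member is scored against it;
the denominator is again the total number of non-missing calls over all
members, so one no-call in a trio of 21-marker profiles gives 62 rather
than 63.

Two aggregate estimates bracket the truth:

* ``all_genuine`` — trust every declared replicate label and count every
  difference as a calling error.  Mislabelled samples masquerading as
  replicates inflate this estimate, making it conservative (an upper
  bound).
* ``diff_threshold`` — treat members differing from their partner or group
  consensus at more than ``threshold`` markers (default 2) as mislabelled,
  exclude them symmetrically, and count errors among what remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError, UndefinedResultError, ValidationError
from .types import MISSING, GenotypeMatrix

#: members differing from consensus/partner at more than this many markers
#: are presumed mislabelled under the diff_threshold assumption
DEFAULT_DIFF_THRESHOLD = 2


@dataclass
class ReplicateGroup:
    """Declared replicates of one variety: a label plus member profiles."""

    label: str
    members: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        lengths = {np.asarray(p).size for _, p in self.members}
        if len(lengths) > 1:
            raise ValidationError(
                f"group {self.label!r}: member profiles differ in length"
            )

    @property
    def size(self) -> int:
        return len(self.members)


def replicate_groups_from_matrix(
    matrix: GenotypeMatrix,
    replicate_labels: Mapping[str, str] | None = None,
    min_size: int = 2,
) -> list[ReplicateGroup]:
    """Build replicate groups from sample metadata or an explicit mapping.

    Samples whose label occurs fewer than ``min_size`` times are left out.
    Editing the mapping beforehand is how known homonyms (same name,
    registry-confirmed distinct genotypes) are excluded from estimation.
    """
    labels = replicate_labels if replicate_labels is not None else matrix.replicate_labels()
    by_label: dict[str, list[str]] = {}
    for sid in matrix.sample_ids:
        lab = labels.get(sid)
        if lab is not None:
            by_label.setdefault(lab, []).append(sid)
    out = []
    for lab in sorted(by_label):
        sids = by_label[lab]
        if len(sids) < min_size:
            continue
        out.append(
            ReplicateGroup(
                label=lab,
                members=[(sid, matrix.profile(sid).copy()) for sid in sids],
            )
        )
    return out


def pairwise_differences(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """Count differing and comparable positions between two profiles.

    A position is comparable when both calls are non-missing; it differs
    when additionally the states differ.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"profile length mismatch: {a.size} vs {b.size}")
    both = (a >= 0) & (b >= 0)
    return int(np.count_nonzero(both & (a != b))), int(np.count_nonzero(both))


def consensus_profile(group: ReplicateGroup) -> np.ndarray:
    """Per-marker strict-majority state over a group of >= 3 profiles.

    At each marker, the state held by a strict majority of the non-missing
    calls wins; with no strict majority (e.g. three members, three
    different states) the consensus is a no-call there, and the marker is
    skipped in downstream error counting.
    """
    if group.size < 3:
        raise ParameterError(
            "consensus needs >= 3 members; compare pairs with pairwise_differences"
        )
    profiles = np.stack([np.asarray(p) for _, p in group.members])
    m = profiles.shape[1]
    out = np.full(m, MISSING, dtype=np.int8)
    for j in range(m):
        col = profiles[:, j]
        col = col[col >= 0]
        if col.size == 0:
            continue
        vals, counts = np.unique(col, return_counts=True)
        top = np.argmax(counts)
        if counts[top] * 2 > col.size:
            out[j] = vals[top]
    return out


@dataclass
class GroupError:
    """Error bookkeeping for one replicate group."""

    label: str
    errors: int
    total_calls: int
    member_diffs: dict[str, int]

    @property
    def rate(self) -> float:
        return self.errors / self.total_calls if self.total_calls else float("nan")


def group_error(group: ReplicateGroup) -> GroupError:
    """Errors, total calls and rate for one replicate group.

    Pairs: errors = differing positions; total calls = non-missing calls
    summed over both members.  Groups of three or more: each member is
    scored against the strict-majority consensus (markers whose consensus
    is a no-call are skipped); total calls = non-missing calls summed over
    all members.
    """
    if group.size < 2:
        raise ParameterError("error estimation needs >= 2 members")
    profiles = [np.asarray(p) for _, p in group.members]
    total_calls = int(sum(np.count_nonzero(p >= 0) for p in profiles))
    if group.size == 2:
        d, _ = pairwise_differences(profiles[0], profiles[1])
        member_diffs = {sid: d for sid, _ in group.members}
        return GroupError(group.label, d, total_calls, member_diffs)
    cons = consensus_profile(group)
    errors = 0
    member_diffs = {}
    for (sid, _), p in zip(group.members, profiles):
        d, _ = pairwise_differences(p, cons)
        member_diffs[sid] = d
        errors += d
    return GroupError(group.label, errors, total_calls, member_diffs)


@dataclass
class ErrorEstimate:
    """Aggregate error-rate estimate over many replicate groups."""

    errors: int
    total_calls: int
    assumption: str
    threshold: int | None
    per_group: list[GroupError] = field(default_factory=list)
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)

    @property
    def rate(self) -> float:
        return self.errors / self.total_calls if self.total_calls else float("nan")


def overall_error_rate(
    groups: Sequence[ReplicateGroup],
    assumption: str = "all_genuine",
    threshold: int = DEFAULT_DIFF_THRESHOLD,
) -> ErrorEstimate:
    """Pool error counts over replicate groups under one of two assumptions.

    ``all_genuine``: every declared replicate is trusted; every difference
    counts.  ``diff_threshold``: members differing from their group
    consensus (or partner, for pairs) at more than ``threshold`` markers
    are presumed mislabelled and excluded — both members of a discordant
    pair are dropped, since neither can be presumed correct; groups reduced
    below two members drop out entirely.  Exclusions are logged.
    """
    if assumption not in ("all_genuine", "diff_threshold"):
        raise ParameterError(f"unknown assumption {assumption!r}")
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    if not groups:
        raise UndefinedResultError("no replicate groups supplied")

    per_group: list[GroupError] = []
    excluded: list[tuple[str, str]] = []

    for g in groups:
        if g.size < 2:
            excluded.extend(
                (sid, f"group {g.label!r} has fewer than 2 members") for sid, _ in g.members
            )
            continue
        if assumption == "all_genuine":
            per_group.append(group_error(g))
            continue
        # diff_threshold: screen out presumed mislabels, then re-score
        if g.size == 2:
            d, _ = pairwise_differences(g.members[0][1], g.members[1][1])
            if d > threshold:
                for sid, _ in g.members:
                    excluded.append(
                        (sid, f"pair differs at {d} markers (> {threshold}); "
                              f"neither member can be presumed correct")
                    )
                continue
            per_group.append(group_error(g))
            continue
        cons = consensus_profile(g)
        keep = []
        for sid, p in g.members:
            d, _ = pairwise_differences(np.asarray(p), cons)
            if d > threshold:
                excluded.append(
                    (sid, f"differs from group consensus at {d} markers (> {threshold})")
                )
            else:
                keep.append((sid, p))
        if len(keep) < 2:
            for sid, _ in keep:
                excluded.append((sid, f"group {g.label!r} reduced below 2 members"))
            continue
        per_group.append(group_error(ReplicateGroup(label=g.label, members=keep)))

    if not per_group:
        raise UndefinedResultError(
            "no replicate group of size >= 2 survives the exclusions"
        )
    errors = sum(ge.errors for ge in per_group)
    total = sum(ge.total_calls for ge in per_group)
    return ErrorEstimate(
        errors=errors,
        total_calls=total,
        assumption=assumption,
        threshold=threshold if assumption == "diff_threshold" else None,
        per_group=per_group,
        excluded_samples=excluded,
    )


__all__ = [
    "DEFAULT_DIFF_THRESHOLD",
    "ReplicateGroup",
    "GroupError",
    "ErrorEstimate",
    "replicate_groups_from_matrix",
    "pairwise_differences",
    "consensus_profile",
    "group_error",
    "overall_error_rate",
]
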