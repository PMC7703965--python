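"""Greedy selection of a minimal discriminating SNP marker subset.

The panel-selection problem is a set cover over sample pairs: each marker
"covers" (discriminates) the pairs of samples whose called genotype states
differ at that marker; a panel is sufficient when every pair that any
marker can split is split by at least one selected marker.  The greedy
heuristic seeds with the marker of highest minor allele frequency, then
repeatedly adds the marker that splits the most still-unresolved pairs,
stopping when nothing improves or every splittable pair is split.

Pairs where either call is missing are never counted as discriminated: a
no-call is unknowable, not a difference.  A heterozygote versus either
homozygote *is* a difference — comparison is on genotype state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedResultError, ValidationError
from .types import GenotypeMatrix, MarkerInfo

#: pairs processed per chunk when accumulating gains (bounds peak memory)
_PAIR_CHUNK = 200_000


def minor_allele_frequency(column: np.ndarray) -> float:
    """Minor allele frequency of one marker column of call codes.

    Alleles are counted over non-missing calls (hom-X contributes two X,
    het one of each, hom-Y two Y); the result is
    ``min(count_X, count_Y) / total`` and lies in ``[0, 0.5]``.
    """
    col = np.asarray(column)
    called = col[col >= 0]
    if called.size == 0:
        raise UndefinedResultError("all calls missing; MAF undefined")
    n_hom_x = int(np.count_nonzero(called == 0))
    n_het = int(np.count_nonzero(called == 1))
    n_hom_y = int(np.count_nonzero(called == 2))
    count_x = 2 * n_hom_x + n_het
    count_y = 2 * n_hom_y + n_het
    return min(count_x, count_y) / (count_x + count_y)


def discriminated_pairs(column: np.ndarray) -> set[tuple[int, int]]:
    """Sample-index pairs split by one marker column.

    Pair ``(i, j)`` (``i < j``) is included iff both calls are non-missing
    and their states differ.
    """
    col = np.asarray(column)
    n = col.size
    out: set[tuple[int, int]] = set()
    for i in range(n):
        if col[i] < 0:
            continue
        for j in range(i + 1, n):
            if col[j] >= 0 and col[i] != col[j]:
                out.add((i, j))
    return out


@dataclass
class SelectionResult:
    """Outcome of a greedy (or augmented) panel selection.

    ``gains[k]`` is the number of previously unresolved pairs newly split
    by ``selected[k]``; ``residual_unresolved`` lists sample-ID pairs that
    remain unsplit when selection stops (for a complete run these are pairs
    no marker in the matrix can split — clones, as far as the panel is
    concerned).
    """

    selected: list[str]
    gains: list[int]
    residual_unresolved: list[tuple[str, str]]
    total_pairs: int

    @property
    def resolved_count(self) -> int:
        return self.total_pairs - len(self.residual_unresolved)


def _pair_arrays(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    return iu.astype(np.int32), ju.astype(np.int32)


def _gains_over_pairs(
    calls: np.ndarray, iu: np.ndarray, ju: np.ndarray
) -> np.ndarray:
    """For every marker, count the given pairs it discriminates (chunked)."""
    m = calls.shape[1]
    gains = np.zeros(m, dtype=np.int64)
    for start in range(0, iu.size, _PAIR_CHUNK):
        sl = slice(start, start + _PAIR_CHUNK)
        a = calls[iu[sl], :]
        b = calls[ju[sl], :]
        disc = (a != b) & (a >= 0) & (b >= 0)
        gains += disc.sum(axis=0, dtype=np.int64)
    return gains


def _marker_splits_pairs(
    calls: np.ndarray, j: int, iu: np.ndarray, ju: np.ndarray
) -> np.ndarray:
    a = calls[iu, j]
    b = calls[ju, j]
    return (a != b) & (a >= 0) & (b >= 0)


def greedy_select(
    matrix: GenotypeMatrix, max_panel: int | None = None
) -> SelectionResult:
    """Iteratively build a small panel that splits every splittable pair.

    Step 1 picks the marker with the highest minor allele frequency; each
    later step picks the marker splitting the most still-unresolved pairs.
    Selection stops when no unresolved pair remains, when no remaining
    marker adds a split, or when ``max_panel`` markers have been chosen.

    Ties are broken deterministically: equal pair gain -> higher MAF wins;
    still equal -> lexicographically smaller marker ID.
    """
    n, m = matrix.n_samples, matrix.n_markers
    if n < 2:
        raise ParameterError("need at least two samples to discriminate")
    if m < 1:
        raise ParameterError("need at least one marker")
    if max_panel is not None and max_panel < 1:
        raise ParameterError("max_panel must be >= 1")

    calls = matrix.calls
    marker_ids = matrix.marker_ids
    mafs = np.array(
        [
            minor_allele_frequency(calls[:, j]) if (calls[:, j] >= 0).any() else -1.0
            for j in range(m)
        ]
    )

    iu, ju = _pair_arrays(n)
    unresolved_iu, unresolved_ju = iu, ju
    total_pairs = iu.size

    remaining = list(range(m))
    selected: list[str] = []
    gains: list[int] = []

    # step 1: MAF seeding
    first = min(remaining, key=lambda j: (-mafs[j], marker_ids[j]))
    split = _marker_splits_pairs(calls, first, unresolved_iu, unresolved_ju)
    selected.append(marker_ids[first])
    gains.append(int(split.sum()))
    unresolved_iu, unresolved_ju = unresolved_iu[~split], unresolved_ju[~split]
    remaining.remove(first)

    while unresolved_iu.size and remaining:
        if max_panel is not None and len(selected) >= max_panel:
            break
        g = _gains_over_pairs(calls[:, remaining], unresolved_iu, unresolved_ju)
        best_gain = g.max()
        if best_gain == 0:
            break
        tied = [remaining[k] for k in np.nonzero(g == best_gain)[0]]
        best = min(tied, key=lambda j: (-mafs[j], marker_ids[j]))
        split = _marker_splits_pairs(calls, best, unresolved_iu, unresolved_ju)
        selected.append(marker_ids[best])
        gains.append(int(best_gain))
        unresolved_iu, unresolved_ju = unresolved_iu[~split], unresolved_ju[~split]
        remaining.remove(best)

    sample_ids = matrix.sample_ids
    residual = [
        (sample_ids[i], sample_ids[j])
        for i, j in zip(unresolved_iu.tolist(), unresolved_ju.tolist())
    ]
    return SelectionResult(
        selected=selected,
        gains=gains,
        residual_unresolved=residual,
        total_pairs=total_pairs,
    )


@dataclass
class RankedMarker:
    marker_id: str
    differentiation_score: int
    chromosome: str | None


def rank_and_augment(
    matrix: GenotypeMatrix,
    selection: SelectionResult,
    marker_info: list[MarkerInfo] | None = None,
) -> tuple[list[RankedMarker], SelectionResult]:
    """Rank unselected markers and extend the panel to cover all chromosomes.

    The differentiation score of an unselected marker is the number of
    pairs left unresolved by ``selection`` that the marker would split.
    Augmentation walks the ranking and appends the top-scoring marker from
    each chromosome not yet represented in the panel, until every
    chromosome present in ``marker_info`` is covered or no candidate
    remains.
    """
    if marker_info is None:
        marker_info = matrix.markers
    by_id = {m.marker_id: m for m in marker_info}
    missing_chrom = [m.marker_id for m in marker_info if m.chromosome is None]
    if missing_chrom:
        raise ValidationError(
            f"cannot augment by chromosome: markers without a chromosome "
            f"label: {missing_chrom[:5]}"
        )

    sid_pos = {sid: i for i, sid in enumerate(matrix.sample_ids)}
    res_iu = np.array([sid_pos[a] for a, _ in selection.residual_unresolved], dtype=np.int32)
    res_ju = np.array([sid_pos[b] for _, b in selection.residual_unresolved], dtype=np.int32)

    chosen = set(selection.selected)
    ranking: list[RankedMarker] = []
    for j, mid in enumerate(matrix.marker_ids):
        if mid in chosen:
            continue
        if res_iu.size:
            score = int(_marker_splits_pairs(matrix.calls, j, res_iu, res_ju).sum())
        else:
            score = 0
        ranking.append(RankedMarker(mid, score, by_id[mid].chromosome))
    ranking.sort(key=lambda r: (-r.differentiation_score, r.marker_id))

    all_chroms = {m.chromosome for m in marker_info}
    covered = {by_id[mid].chromosome for mid in selection.selected if mid in by_id}
    selected = list(selection.selected)
    gains = list(selection.gains)
    res_iu_cur, res_ju_cur = res_iu, res_ju
    for r in ranking:
        if covered >= all_chroms:
            break
        if r.chromosome in covered:
            continue
        j = matrix.marker_ids.index(r.marker_id)
        if res_iu_cur.size:
            split = _marker_splits_pairs(matrix.calls, j, res_iu_cur, res_ju_cur)
            gain = int(split.sum())
            res_iu_cur, res_ju_cur = res_iu_cur[~split], res_ju_cur[~split]
        else:
            gain = 0
        selected.append(r.marker_id)
        gains.append(gain)
        covered.add(r.chromosome)

    sample_ids = matrix.sample_ids
    residual = [
        (sample_ids[i], sample_ids[j])
        for i, j in zip(res_iu_cur.tolist(), res_ju_cur.tolist())
    ]
    augmented = SelectionResult(
        selected=selected,
        gains=gains,
        residual_unresolved=residual,
        total_pairs=selection.total_pairs,
    )
    return ranking, augmented


@dataclass
class MinimumPanelResult:
    """Result of exhaustive minimum-panel search.

    ``markers`` is a smallest subset splitting every splittable pair, or
    ``None`` when no subset within ``max_size`` does (``reason`` says why).
    """

    markers: list[str] | None
    reason: str | None = None
    resolvable_pairs: int = 0


def brute_force_minimum_panel(
    matrix: GenotypeMatrix, max_size: int, subset_guard: int = 1_000_000
) -> MinimumPanelResult:
    """Exhaustively find a minimum-cardinality discriminating marker subset.

    Searches subset sizes in increasing order; within a size, subsets are
    visited in lexicographic order of sorted marker IDs, so ties resolve
    deterministically.  Intended as an independent check of
    :func:`greedy_select` on small instances; refuses instances where the
    enumeration would exceed ``subset_guard`` subsets.
    """
    n, m = matrix.n_samples, matrix.n_markers
    if n < 2:
        raise ParameterError("need at least two samples")
    if not (1 <= max_size <= m):
        raise ParameterError(f"max_size must be in [1, {m}]")

    total = 0
    for k in range(1, max_size + 1):
        total += _n_choose_k(m, k)
        if total > subset_guard:
            raise ParameterError(
                f"enumeration of subsets up to size {max_size} over {m} markers "
                f"exceeds the {subset_guard} guard; use greedy_select instead"
            )

    iu, ju = _pair_arrays(n)
    order = sorted(range(m), key=lambda j: matrix.marker_ids[j])
    per_marker = {
        j: _marker_splits_pairs(matrix.calls, j, iu, ju) for j in order
    }
    target = np.zeros(iu.size, dtype=bool)
    for mask in per_marker.values():
        target |= mask
    n_resolvable = int(target.sum())
    if n_resolvable == 0:
        return MinimumPanelResult(
            markers=None,
            reason="no marker discriminates any pair",
            resolvable_pairs=0,
        )

    for k in range(1, max_size + 1):
        for combo in itertools.combinations(order, k):
            cover = np.zeros(iu.size, dtype=bool)
            for j in combo:
                cover |= per_marker[j]
            if (cover | ~target).all():
                return MinimumPanelResult(
                    markers=[matrix.marker_ids[j] for j in combo],
                    resolvable_pairs=n_resolvable,
                )
    return MinimumPanelResult(
        markers=None,
        reason=f"no subset of size <= {max_size} covers all resolvable pairs",
        resolvable_pairs=n_resolvable,
    )


def _n_choose_k(n: int, k: int) -> int:
    import math

    return math.comb(n, k)


__all__ = [
    "minor_allele_frequency",
    "discriminated_pairs",
    "SelectionResult",
    "RankedMarker",
    "MinimumPanelResult",
    "greedy_select",
    "rank_and_augment",
    "brute_force_minimum_panel",
]
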