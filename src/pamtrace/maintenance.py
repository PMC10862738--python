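"""Presence calling and clonal-maintenance statistics.

Capture-style deep sequencing gives an alt/total depth pair for every PAM
site in every sample. A site is called present when its VAF reaches the 5%
cutoff (just above background artifact noise), absent below it, and no-call
when depth is too low to decide. No-call entries are excluded from both
numerator and denominator of every statistic.

Statistics follow the multi-region sequencing conventions:

* percent truncal  — per metastasis, fraction of the case's truncal PAMs it
  carries;
* percent maintained — per PAM, fraction of metastases carrying it;
* shared-by-all   — fraction of truncal PAMs carried by every lesion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .loh import LohScope

__all__ = [
    "PresenceMatrix",
    "TruncalSet",
    "MaintenanceReport",
    "call_presence",
    "define_truncal_union",
    "infer_truncal_from_mets",
    "percent_truncal",
    "percent_maintained",
    "shared_by_all",
    "set_overlaps",
    "maintenance_by_loh_class",
    "qc_depth_filter",
    "group_tests",
]

PRESENT, ABSENT, NO_CALL = "present", "absent", "no_call"


def call_presence(alt_depth: int, total_depth: int, vaf_cut: float = 0.05,
                  min_depth: int = 20) -> str:
    """Three-way presence call for one site in one sample.

    ``no_call`` below the depth gate; ``present`` at VAF >= vaf_cut
    (boundary inclusive — a site at exactly the cutoff is present); else
    ``absent``.
    """
    if alt_depth < 0 or total_depth < 0:
        raise ValueError("depths must be non-negative")
    if total_depth < min_depth:
        return NO_CALL
    return PRESENT if alt_depth / total_depth >= vaf_cut else ABSENT


@dataclass
class PresenceMatrix:
    """PAM × sample presence grid with a parallel no-call mask."""

    pam_ids: list[str]
    sample_ids: list[str]
    present: np.ndarray  # bool, shape (n_pams, n_samples)
    no_call: np.ndarray  # bool, same shape; True ⇒ presence entry ignored

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        self.no_call = np.asarray(self.no_call, dtype=bool)
        shape = (len(self.pam_ids), len(self.sample_ids))
        if self.present.shape != shape or self.no_call.shape != shape:
            raise ValueError(
                f"grid shapes {self.present.shape}/{self.no_call.shape} "
                f"do not match ids {shape}"
            )

    @classmethod
    def from_depths(
        cls,
        depths: Mapping[tuple[str, str], tuple[int, int]],
        pam_ids: Sequence[str],
        sample_ids: Sequence[str],
        vaf_cut: float = 0.05,
        min_depth: int = 20,
    ) -> "PresenceMatrix":
        """Build from (pam_id, sample_id) → (alt_depth, total_depth).

        A site/sample pair missing from ``depths`` is a no-call (nothing was
        sequenced there).
        """
        n_p, n_s = len(pam_ids), len(sample_ids)
        present = np.zeros((n_p, n_s), dtype=bool)
        no_call = np.ones((n_p, n_s), dtype=bool)
        for i, p in enumerate(pam_ids):
            for j, s in enumerate(sample_ids):
                pair = depths.get((p, s))
                if pair is None:
                    continue
                call = call_presence(pair[0], pair[1], vaf_cut=vaf_cut,
                                     min_depth=min_depth)
                if call != NO_CALL:
                    no_call[i, j] = False
                    present[i, j] = call == PRESENT
        return cls(list(pam_ids), list(sample_ids), present, no_call)

    def column(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def row(self, pam_id: str) -> int:
        return self.pam_ids.index(pam_id)

    def present_set(self, sample_id: str) -> set[str]:
        j = self.column(sample_id)
        mask = self.present[:, j] & ~self.no_call[:, j]
        return {self.pam_ids[i] for i in np.flatnonzero(mask)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "PresenceMatrix":
        cols = [self.column(s) for s in sample_ids]
        return PresenceMatrix(list(self.pam_ids), list(sample_ids),
                              self.present[:, cols], self.no_call[:, cols])


@dataclass(frozen=True)
class TruncalSet:
    """The case's truncal PAMs and how they were defined."""

    case_id: str
    pam_ids: frozenset[str]
    provenance: str  # primary_union | met_inferred
    uncallable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.provenance not in ("primary_union", "met_inferred"):
            raise ValueError(f"bad provenance {self.provenance!r}")


def define_truncal_union(primary: PresenceMatrix, case_id: str = "") -> TruncalSet:
    """Truncal = union of PAMs present in any primary-tumor sample.

    PAMs that are no-call in every primary (so presence could not be
    evaluated anywhere) are excluded and listed in ``uncallable``.
    """
    if not primary.sample_ids:
        raise ValueError("need at least one primary sample; use "
                         "infer_truncal_from_mets when none exists")
    callable_any = ~primary.no_call.all(axis=1)
    present_any = (primary.present & ~primary.no_call).any(axis=1)
    pam_ids = frozenset(
        p for p, ok in zip(primary.pam_ids, present_any) if ok
    )
    uncallable = frozenset(
        p for p, ok in zip(primary.pam_ids, callable_any) if not ok
    )
    return TruncalSet(case_id=case_id, pam_ids=pam_ids,
                      provenance="primary_union", uncallable=uncallable)


def infer_truncal_from_mets(mets: PresenceMatrix, min_mets: int = 2,
                            case_id: str = "") -> TruncalSet:
    """Truncal inferred as PAMs present in at least ``min_mets`` metastases
    (used when no primary sample exists)."""
    if len(mets.sample_ids) < min_mets:
        raise ValueError(
            f"need >= {min_mets} metastases, have {len(mets.sample_ids)}"
        )
    counts = (mets.present & ~mets.no_call).sum(axis=1)
    callable_any = ~mets.no_call.all(axis=1)
    pam_ids = frozenset(
        p for p, c in zip(mets.pam_ids, counts) if c >= min_mets
    )
    uncallable = frozenset(
        p for p, ok in zip(mets.pam_ids, callable_any) if not ok
    )
    return TruncalSet(case_id=case_id, pam_ids=pam_ids,
                      provenance="met_inferred", uncallable=uncallable)


def percent_truncal(sample_id: str, presence: PresenceMatrix,
                    truncal: TruncalSet) -> float | None:
    """Fraction of the case's truncal PAMs present in one sample.

    No-call PAMs leave both numerator and denominator. Returns None when no
    truncal PAM is evaluable in the sample.
    """
    j = presence.column(sample_id)
    idx = [presence.row(p) for p in truncal.pam_ids if p in presence.pam_ids]
    evaluable = [i for i in idx if not presence.no_call[i, j]]
    if not evaluable:
        return None
    hit = sum(bool(presence.present[i, j]) for i in evaluable)
    return hit / len(evaluable)


def percent_maintained(pam_id: str, presence: PresenceMatrix,
                       met_samples: Sequence[str]) -> float | None:
    """Fraction of metastases in which one PAM is present (evaluable only)."""
    i = presence.row(pam_id)
    cols = [presence.column(s) for s in met_samples]
    evaluable = [j for j in cols if not presence.no_call[i, j]]
    if not evaluable:
        return None
    hit = sum(bool(presence.present[i, j]) for j in evaluable)
    return hit / len(evaluable)


def shared_by_all(truncal: TruncalSet, presence: PresenceMatrix) -> float | None:
    """Fraction of truncal PAMs present (not absent, not no-call) in every
    lesion of the matrix."""
    idx = [presence.row(p) for p in truncal.pam_ids if p in presence.pam_ids]
    if not idx:
        return None
    sub_present = presence.present[idx, :] & ~presence.no_call[idx, :]
    in_all = sub_present.all(axis=1)
    return int(in_all.sum()) / len(idx)


def set_overlaps(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exact counts for every exclusive membership region of 2–7 named sets.

    Returns {frozenset of set names: count of elements in exactly those
    sets}. All 2^n − 1 regions are reported, including empty ones.
    """
    names = list(sets)
    if not 2 <= len(names) <= 7:
        raise ValueError(f"set_overlaps handles 2–7 sets, got {len(names)}")
    universe = set().union(*sets.values())
    regions = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    for x in universe:
        members = frozenset(n for n in names if x in sets[n])
        regions[members] += 1
    return regions


def maintenance_by_loh_class(
    presence: PresenceMatrix,
    truncal: TruncalSet,
    scopes: Iterable[LohScope],
    pam_positions: Mapping[str, tuple[str, int]],
    met_samples: Sequence[str],
) -> pd.DataFrame:
    """Mean per-PAM percent maintained, grouped by the LOH scope of the
    region holding each PAM.

    ``pam_positions`` maps pam_id → (chrom, pos). PAMs falling in no scope
    region land in an "unclassified" row. Classes with no PAMs report count
    0 and a missing mean.
    """
    scope_list = list(scopes)

    def classify(pam_id: str) -> str:
        chrom, pos = pam_positions[pam_id]
        for s in scope_list:
            if s.chrom == chrom and s.start <= pos < s.end:
                return s.scope
        return "unclassified"

    per_class: dict[str, list[float]] = {
        "truncal_loh": [], "private_loh": [], "retained_het": [],
        "unclassified": [],
    }
    for pam_id in sorted(truncal.pam_ids):
        if pam_id not in presence.pam_ids or pam_id not in pam_positions:
            per_class["unclassified"].append(np.nan)
            continue
        pm = percent_maintained(pam_id, presence, met_samples)
        if pm is None:
            continue
        per_class[classify(pam_id)].append(pm)

    rows = []
    for cls in ("truncal_loh", "private_loh", "retained_het", "unclassified"):
        vals = [v for v in per_class[cls] if not np.isnan(v)]
        rows.append({
            "loh_class": cls,
            "n_pams": len(vals),
            "mean_percent_maintained": float(np.mean(vals)) if vals else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC and group tests


def _line_sse(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    coeffs = np.polyfit(x, y, 1)
    resid = y - np.polyval(coeffs, x)
    return float(resid @ resid)


def _hinge_fit(x: np.ndarray, y: np.ndarray, knot: float
               ) -> tuple[float, float, float]:
    """Continuous two-segment least squares with a fixed knot.

    Returns (sse, left_slope, right_slope). Continuity at the knot keeps the
    model from trivially zeroing the SSE on small n.
    """
    left = np.minimum(x, knot) - knot
    right = np.maximum(x - knot, 0.0)
    design = np.column_stack([np.ones_like(x), left, right])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), float(coef[1]), float(coef[2])


def qc_depth_filter(
    per_sample: Mapping[str, tuple[float, float]],
    min_depth: float = 30.0,
) -> dict[str, bool]:
    """Flag samples for inclusion from (mean on-target depth, percent truncal).

    Low-cellularity or shallow samples sit on the rising limb of the percent
    truncal vs depth curve; only samples on the flat ("linear") portion are
    kept. The knee is the breakpoint of a continuous two-segment
    least-squares fit, applied only when depths genuinely spread (max at
    least 1.5x min — equal-depth samples differing in percent truncal are
    biology, not QC), the split clearly beats a single line, and the left
    limb sits lower; samples below max(min_depth, knee) are excluded. With
    fewer than 3 samples, or a degenerate fit, only the depth floor applies.
    """
    names = list(per_sample)
    depths = np.array([per_sample[s][0] for s in names], dtype=float)
    pct = np.array([per_sample[s][1] for s in names], dtype=float)
    knee = -np.inf
    spread = depths.max() >= 1.5 * max(depths.min(), 1e-9)
    if len(names) >= 3 and spread:
        order = np.argsort(depths)
        xs, ys = depths[order], pct[order]
        sse_one = _line_sse(xs, ys)
        if sse_one <= 1e-12:
            warnings.warn("degenerate (collinear) depth/truncal fit; "
                          "threshold-only QC", stacklevel=2)
        else:
            # Candidate knots at interior observed depths; ties favour the
            # smaller knot so borderline samples stay included.
            best: tuple[float, float, float, float] | None = None
            for knot in sorted(set(xs[1:-1])):
                sse, ls, rs = _hinge_fit(xs, ys, float(knot))
                if best is None or sse < best[0] - 1e-15:
                    best = (sse, float(knot), ls, rs)
            if best is not None:
                sse_two, knot, left_slope, right_slope = best
                low = ys[xs < knot]
                if sse_two <= 0.5 * sse_one and left_slope > right_slope \
                        and left_slope > 0 and low.size \
                        and low.mean() < ys[xs >= knot].mean():
                    knee = knot  # first depth on the flat limb
    floor = max(min_depth, knee)
    return {s: bool(per_sample[s][0] >= floor) for s in names}


def group_tests(groups: Mapping[str, Sequence[float]]) -> dict:
    """Nonparametric and parametric comparisons between labelled groups.

    Two groups: two-sided Mann-Whitney rank-sum (exact where SciPy can).
    Three or more: Kruskal-Wallis plus one-way ANOVA. Degenerate inputs
    (every value identical) report missing p-values with a warning. Raw
    p-values; no multiple-testing correction (flagged in the output).
    """
    labels = list(groups)
    if len(labels) < 2 or any(len(groups[k]) < 2 for k in labels):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    out: dict = {"groups": labels,
                 "n": {k: len(groups[k]) for k in labels},
                 "multiple_testing_correction": "none"}
    flat = np.concatenate(arrays)
    degenerate = np.allclose(flat, flat[0])
    if len(labels) == 2:
        if degenerate:
            warnings.warn("all values identical; rank-sum p undefined",
                          stacklevel=2)
            out["mann_whitney"] = {"statistic": np.nan, "p_value": np.nan}
        else:
            method = "exact" if len(flat) <= 20 else "auto"
            res = stats.mannwhitneyu(arrays[0], arrays[1],
                                     alternative="two-sided", method=method)
            out["mann_whitney"] = {"statistic": float(res.statistic),
                                   "p_value": float(res.pvalue)}
    else:
        if degenerate:
            warnings.warn("all values identical; group tests undefined",
                          stacklevel=2)
            out["kruskal_wallis"] = {"statistic": np.nan, "p_value": np.nan}
            out["anova"] = {"statistic": np.nan, "p_value": np.nan}
        else:
            kw = stats.kruskal(*arrays)
            out["kruskal_wallis"] = {"statistic": float(kw.statistic),
                                     "p_value": float(kw.pvalue)}
            try:
                an = stats.f_oneway(*arrays)
                out["anova"] = {"statistic": float(an.statistic),
                                "p_value": float(an.pvalue)}
            except Exception:
                out["anova"] = {"statistic": np.nan, "p_value": np.nan}
    return out


@dataclass
class MaintenanceReport:
    """Case-level maintenance summary."""

    case_id: str
    percent_truncal: dict[str, float | None]
    percent_maintained: dict[str, float | None]
    shared_all: float | None
    by_loh_class: pd.DataFrame | None = None

    @property
    def mean_percent_truncal(self) -> float | None:
        vals = [v for v in self.percent_truncal.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_percent_maintained(self) -> float | None:
        vals = [v for v in self.percent_maintained.values() if v is not None]
        return float(np.mean(vals)) if vals else None
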