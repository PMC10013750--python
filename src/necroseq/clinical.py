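"""Longitudinal CTC analytics and plasma-proteomics comparisons.

Covers the clinical arm of the pipeline: low-to-high CTC transition
detection (>= 10-fold rise between timepoints, >= 20 CTCs marks a
high-count sample), waterfall summaries of per-subject changes, the
Benjamini-Krieger-Yekutieli two-stage adaptive FDR, high-vs-low-CTC plasma
protein enrichment, paired >= 2-fold protein fractions, cohort prevalence
summaries, and the caliper tumor-volume utility V = W^2 * L / 2.

CTC tables are tidy data frames with columns ``subject``, ``timepoint``,
``single_ctc`` and (optionally) ``ctc_cluster``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PlasmaTable


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Estimated caliper tumor volume V = W^2 * L / 2 (mm^3); W is the
    shorter axis, so W > L is rejected rather than silently swapped."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("caliper measurements must be positive")
    if width_mm > length_mm:
        raise ValueError("W must be the shorter axis (W <= L)")
    return width_mm**2 * length_mm / 2.0


# ---------------------------------------------------------------------------
# CTC dynamics


def detect_transitions(
    counts,
    fold_threshold: float = 10.0,
    high_count_threshold: int = 20,
    floor: int = 1,
    absolute: bool = False,
) -> dict:
    """Flag low-to-high transitions in one subject's ordered CTC counts.

    A consecutive pair is flagged when the later count is at least
    ``fold_threshold`` times max(earlier, floor) — the floor makes the fold
    well defined at zero baselines. With ``absolute=True`` the threshold is
    an absolute increase instead. Samples with at least
    ``high_count_threshold`` CTCs are flagged high.
    """
    c = np.asarray(list(counts), float)
    if absolute:
        pair_flags = [bool(c[i + 1] - c[i] >= fold_threshold) for i in range(len(c) - 1)]
    else:
        pair_flags = [
            bool(c[i + 1] >= fold_threshold * max(c[i], floor)) for i in range(len(c) - 1)
        ]
    high_flags = [bool(x >= high_count_threshold) for x in c]
    return {
        "pair_flags": pair_flags,
        "high_flags": high_flags,
        "any_transition": any(pair_flags),
    }


def waterfall_changes(ctc: pd.DataFrame, floor: int = 1, mode: str = "first_last") -> pd.DataFrame:
    """Per-subject CTC change between time points, sorted by magnitude.

    Default compares each subject's first and last timepoint (configurable
    to the largest consecutive-pair change with ``mode='consecutive'``).
    Rows are sorted by descending delta, ties broken by subject id.
    """
    if mode not in {"first_last", "consecutive"}:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for subject, grp in ctc.sort_values("timepoint").groupby("subject"):
        c = grp["single_ctc"].to_numpy(float)
        if len(c) < 2:
            raise ValueError(f"subject {subject} has fewer than 2 timepoints")
        if mode == "first_last":
            early, late = c[0], c[-1]
        else:
            i = int(np.argmax(c[1:] - c[:-1]))
            early, late = c[i], c[i + 1]
        rows.append(
            {
                "subject": subject,
                "early": early,
                "late": late,
                "delta": late - early,
                "fold": late / max(early, floor),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["delta", "subject"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def prevalence_summary(ctc: pd.DataFrame) -> dict:
    """Cohort prevalence of CTC positivity: subjects with >= 1 CTC ever
    (singles or clusters), with >= 1 cluster ever, and with no CTCs ever.

    Percentages are of the subject count, rounded half-up; unrounded values
    are reported alongside so the complementary pair reconciles exactly.
    """
    if ctc.empty:
        raise ValueError("empty cohort")
    per = ctc.groupby("subject").agg(
        single=("single_ctc", "sum"),
        cluster=("ctc_cluster", "sum") if "ctc_cluster" in ctc else ("single_ctc", lambda s: 0),
    )
    n = len(per)
    n_ctc = int(((per["single"] > 0) | (per["cluster"] > 0)).sum())
    n_cluster = int((per["cluster"] > 0).sum())
    n_none = n - n_ctc
    return {
        "n_subjects": n,
        "n_ctc_ever": n_ctc,
        "pct_ctc_ever": _round_half_up(100.0 * n_ctc / n),
        "pct_ctc_ever_unrounded": 100.0 * n_ctc / n,
        "n_cluster_ever": n_cluster,
        "pct_cluster_ever": _round_half_up(100.0 * n_cluster / n),
        "pct_cluster_ever_unrounded": 100.0 * n_cluster / n,
        "n_no_ctc_ever": n_none,
        "pct_no_ctc_ever": _round_half_up(100.0 * n_none / n),
        "pct_no_ctc_ever_unrounded": 100.0 * n_none / n,
    }


# ---------------------------------------------------------------------------
# two-stage BKY FDR


def bky_fdr(p_values, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Krieger-Yekutieli two-stage linear step-up.

    Stage 1 runs BH at level q/(1+q) yielding r1 rejections; with
    0 < r1 < m, stage 2 re-runs BH at level q/(1+q) * m/(m-r1) (the
    adaptive null-count estimate m0 = m - r1). Returns ``(q_values,
    discovery_flags)`` in input order; a protein is a discovery iff its
    adjusted q-value is <= q.
    """
    p = np.asarray(list(p_values), float)
    bad = np.where(~((p >= 0) & (p <= 1)))[0]
    if bad.size:
        raise ValueError(f"p-value out of [0, 1] at index {int(bad[0])}")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q1 = q / (1.0 + q)
    below = ps <= q1 * ranks / m
    r1 = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0
    m0 = m - r1 if 0 < r1 < m else m
    raw = ps * (1.0 + q) * m0 / ranks
    q_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    qvals = np.empty(m)
    qvals[order] = q_sorted
    return qvals, qvals <= q


# ---------------------------------------------------------------------------
# plasma proteomics


def group_protein_enrichment(
    plasma: PlasmaTable, q: float = 0.10, moderate: bool = True
) -> pd.DataFrame:
    """High-vs-low-CTC protein enrichment with BKY discovery flags.

    Per protein: log2FC = mean(high) - mean(low), a moderated two-sample t
    p-value (empirical-Bayes variance shrinkage across proteins, which keeps
    the extreme tail calibrated at very small group sizes; ``moderate=False``
    drops to a plain Welch t), BKY two-stage q-value, discovery at
    q-value <= q. A degenerate protein (zero variance in both groups, equal
    means) gets p = 1 by convention.
    """
    from .enrich import _test_rows

    state = plasma.sample_meta["ctc_state"]
    high = plasma.abundance.loc[:, (state == "high").to_numpy()]
    low = plasma.abundance.loc[:, (state == "low").to_numpy()]
    if high.shape[1] < 2 or low.shape[1] < 2:
        raise ValueError("need >= 2 samples per CTC state")
    lfc, p = _test_rows(high.to_numpy(float), low.to_numpy(float), moderate)
    qvals, flags = bky_fdr(p, q=q)
    return pd.DataFrame(
        {"log2fc": lfc, "p": p, "q": qvals, "discovery": flags},
        index=plasma.abundance.index.rename("protein"),
    )


def paired_fold_change_fraction(
    plasma: PlasmaTable,
    fold_threshold: float = 2.0,
    annotation_set: set[str] | None = None,
) -> dict:
    """Fraction of late-vs-early increased proteins carrying an annotation.

    Each subject must contribute one early and one late sample. Per protein
    the linear late/early fold is averaged over subjects; proteins with mean
    fold >= threshold are the increased set, and the reported percent is the
    half-up-rounded share of them found in ``annotation_set`` (e.g. a
    curated necrosis-associated list). With no increased protein the percent
    is undefined (None).
    """
    meta = plasma.sample_meta
    for col in ("subject", "timepoint"):
        if col not in meta.columns:
            raise ValueError(f"paired analysis requires a {col!r} sample label")
    folds = []
    for subject, grp in meta.groupby("subject"):
        early = grp.index[grp["timepoint"] == "early"]
        late = grp.index[grp["timepoint"] == "late"]
        if len(early) != 1 or len(late) != 1:
            raise ValueError(f"subject {subject} lacks a paired early/late sample")
        folds.append(
            2.0 ** (plasma.abundance[late[0]] - plasma.abundance[early[0]])
        )
    mean_fold = pd.concat(folds, axis=1).mean(axis=1)
    increased = list(mean_fold.index[mean_fold >= fold_threshold])
    annotation_set = set(annotation_set or ())
    n_annotated = len(annotation_set.intersection(increased))
    percent = _round_half_up(100.0 * n_annotated / len(increased)) if increased else None
    return {
        "n_increased": len(increased),
        "increased_proteins": increased,
        "n_annotated": n_annotated,
        "percent_annotated": percent,
        "mean_fold": mean_fold,
    }
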