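"""Ortholog-mapped four-way differential enrichment and gene-set scoring.

The core analysis crosses two axes — tumor core vs rim, and graft (tumor)
vs host transcriptome — on log2 counts-per-million, selects genes that are
significant on both axes at a dual FDR threshold, summarizes linear-scale
folds for single genes, and scores gene sets between conditions with a
size-matched permutation test. Direction convention, stated in every output
header: log2FC core:rim > 0 means core-enriched; log2FC tumor:host > 0
means tumor-enriched.

The per-gene test is a two-sample t on log-CPM with empirical-Bayes
variance moderation (the limma-style scaled-inverse-chi-square prior fitted
across genes), which restores power at small replicate numbers; q-values
are Benjamini-Hochberg within each contrast. The test sits behind a single
interface (:func:`_test_rows`) and can be dropped to a plain Welch t with
``moderate=False``, or swapped for a count-model test.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import SpeciesCountMatrix

logger = logging.getLogger(__name__)

DIRECTION_HEADER = (
    "# direction convention: lfc_core_rim_* > 0 = core-enriched; "
    "lfc_tumor_host_* > 0 = tumor-enriched"
)

CONTRASTS = ("core_rim_graft", "core_rim_host", "tumor_host_core", "tumor_host_rim")


def normalize_counts(
    mat: SpeciesCountMatrix | pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """log2 counts-per-million: log2(1e6*(count+pc) / (libsize + pc*n_genes)).

    The pseudocount keeps all values (and downstream fold-changes) finite
    with zero counts; with pseudocount 0 the transform is exactly scale
    invariant.
    """
    counts = mat.counts if isinstance(mat, SpeciesCountMatrix) else mat
    lib = counts.sum(axis=0).astype(float)
    denom = lib + pseudocount * counts.shape[0]
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return np.log2(1e6 * (counts + pseudocount) / denom)


def map_orthologs(
    host: SpeciesCountMatrix, ortholog_map: dict[str, str]
) -> SpeciesCountMatrix:
    """Re-key host genes by their graft ortholog; many-to-one maps are
    summed, unmapped host genes dropped (and recorded in
    ``counts.attrs['dropped_genes']``).
    """
    mapped_index = host.counts.index.map(ortholog_map)
    keep = mapped_index.notna()
    dropped = list(host.counts.index[~keep])
    if not keep.any():
        raise ValueError("ortholog map covers no host gene")
    if dropped:
        logger.info("dropping %d unmapped host genes: %s%s", len(dropped), dropped[:5],
                    "..." if len(dropped) > 5 else "")
    counts = host.counts[keep].groupby(mapped_index[keep]).sum()
    counts.index.name = "gene"
    counts.attrs["dropped_genes"] = dropped
    return SpeciesCountMatrix(counts, host.species, host.sample_meta)


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t on two (genes x samples) blocks -> (lfc, p).

    Zero variance in both groups with equal means gives p = 1 by
    convention; with unequal means the t statistic is infinite and p = 0.
    """
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    p = np.asarray(p, float)
    p[np.isnan(p) & (lfc == 0)] = 1.0
    p[np.isnan(p)] = 0.0
    return lfc, p


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-8 * x:
            break
    return x


def _moderated_t_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise moderated two-sample t (pooled variance, empirical Bayes).

    Per-gene pooled variances are shrunk toward a scaled-inverse-chi-square
    prior whose scale s0^2 and degrees of freedom d0 are fitted across genes
    by matching the moments of log s^2; the t statistic then has d + d0
    degrees of freedom. With only sampling scatter among the log variances
    the prior is effectively degenerate (d0 -> inf) and all genes share the
    common variance.
    """
    n1, n2 = a.shape[1], b.shape[1]
    d = n1 + n2 - 2
    lfc = a.mean(axis=1) - b.mean(axis=1)
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / d
    s2 = np.maximum(s2, 1e-12)
    e = np.log(s2)
    tri_d = float(polygamma(1, d / 2))
    resid = float(e.var(ddof=1)) - tri_d if e.size > 1 else 0.0
    if resid > 0:
        d0 = 2.0 * _trigamma_inverse(resid)
        log_s0 = (
            float(e.mean())
            - float(digamma(d / 2))
            + math.log(d / 2)
            + float(digamma(d0 / 2))
            - math.log(d0 / 2)
        )
        s2_post = (d0 * math.exp(log_s0) + d * s2) / (d0 + d)
        df = min(d + d0, 1e6)
    else:  # variances indistinguishable from a shared value
        log_s0 = float(e.mean()) - float(digamma(d / 2)) + math.log(d / 2)
        s2_post = np.full_like(s2, math.exp(log_s0))
        df = 1e6
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.asarray(p, float)
    p[np.isnan(p) & (lfc == 0)] = 1.0
    p[np.isnan(p)] = 0.0
    return lfc, p


def _test_rows(a: np.ndarray, b: np.ndarray, moderate: bool = True) -> tuple[np.ndarray, np.ndarray]:
    return _moderated_t_rows(a, b) if moderate else _welch_rows(a, b)


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def differential_enrichment(
    graft: SpeciesCountMatrix,
    host: SpeciesCountMatrix,
    pseudocount: float = 0.5,
    condition: str | None = None,
    moderate: bool = True,
) -> pd.DataFrame:
    """Four-contrast enrichment table on the shared (ortholog-mapped) genes.

    Contrasts: core:rim within each species, tumor:host within each
    compartment. Each needs >= 2 samples per group; a thinner contrast is
    marked unavailable (NaN columns, listed in ``attrs['unavailable']``)
    rather than silently skipped. q-values are BH within each contrast.
    """
    if condition is not None:
        graft, host = graft.select(condition=condition), host.select(condition=condition)
    genes = graft.counts.index.intersection(host.counts.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between graft and host matrices")
    ln = {
        "graft": normalize_counts(
            SpeciesCountMatrix(graft.counts.loc[genes], "graft", graft.sample_meta), pseudocount
        ),
        "host": normalize_counts(
            SpeciesCountMatrix(host.counts.loc[genes], "host", host.sample_meta), pseudocount
        ),
    }
    meta = {"graft": graft.sample_meta, "host": host.sample_meta}

    def block(species: str, compartment: str) -> np.ndarray:
        cols = meta[species].index[meta[species]["compartment"] == compartment]
        return ln[species][cols].to_numpy()

    table = pd.DataFrame(index=genes.rename("gene"))
    for sp in ("graft", "host"):
        for comp in ("core", "rim"):
            table[f"mean_{sp}_{comp}"] = block(sp, comp).mean(axis=1)
    specs = {
        "core_rim_graft": (block("graft", "core"), block("graft", "rim")),
        "core_rim_host": (block("host", "core"), block("host", "rim")),
        "tumor_host_core": (block("graft", "core"), block("host", "core")),
        "tumor_host_rim": (block("graft", "rim"), block("host", "rim")),
    }
    unavailable = []
    for name, (a, b) in specs.items():
        if a.shape[1] < 2 or b.shape[1] < 2:
            unavailable.append(name)
            logger.warning("contrast %s unavailable: fewer than 2 samples per group", name)
            table[f"lfc_{name}"] = np.nan
            table[f"p_{name}"] = np.nan
            table[f"q_{name}"] = np.nan
            continue
        lfc, p = _test_rows(a, b, moderate)
        table[f"lfc_{name}"] = lfc
        table[f"p_{name}"] = p
        table[f"q_{name}"] = _bh(p)
    table.attrs["unavailable"] = unavailable
    table.attrs["direction"] = DIRECTION_HEADER
    return table


def condition_contrast(
    mat_a: SpeciesCountMatrix, mat_b: SpeciesCountMatrix, pseudocount: float = 0.5,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-gene A-vs-B enrichment (e.g. knockdown vs control) on log-CPM.

    Columns: mean_a, mean_b, lfc (A minus B), p, q.
    """
    genes = mat_a.counts.index.intersection(mat_b.counts.index)
    a = normalize_counts(mat_a.counts.loc[genes], pseudocount).to_numpy()
    b = normalize_counts(mat_b.counts.loc[genes], pseudocount).to_numpy()
    lfc, p = _test_rows(a, b, moderate)
    return pd.DataFrame(
        {
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "lfc": lfc,
            "p": p,
            "q": _bh(p),
        },
        index=genes.rename("gene"),
    )


# ---------------------------------------------------------------------------
# gene sets


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    derivation: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def write_gmt(self, path: str | Path) -> None:
        if not self.genes:
            raise ValueError("refusing to persist an empty gene set")
        desc = ";".join(f"{k}={v}" for k, v in self.derivation.items()) or "na"
        Path(path).write_text(f"{self.name}\t{desc}\t" + "\t".join(self.genes) + "\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSet":
        name, desc, *genes = Path(path).read_text().rstrip("\n").split("\t")
        return cls(name, genes, {"source": desc})


_DIRECTIONS = {"up", "down", None}


def select_dual_significant(
    table: pd.DataFrame,
    fdr_threshold: float = 0.01,
    directions: dict[str, str | None] | None = None,
    core_rim_axis: str = "graft",
    tumor_host_axis: str = "core",
    name: str = "dual_significant",
) -> GeneSet:
    """Genes significant on BOTH axes (core:rim and tumor:host) at the FDR
    threshold, optionally sign-filtered per axis.

    ``directions`` maps axis name ("core_rim", "tumor_host") to "up", "down"
    or None; e.g. {"core_rim": "up", "tumor_host": "up"} keeps core-enriched
    tumor-specific genes. Members are ordered by descending combined
    enrichment (sum of the two axis log2FCs, sign-adjusted to the requested
    directions).
    """
    directions = dict(directions or {})
    for axis, d in directions.items():
        if axis not in {"core_rim", "tumor_host"}:
            raise ValueError(f"unknown axis {axis!r}")
        if d not in _DIRECTIONS:
            raise ValueError(f"unknown direction keyword {d!r}; use 'up', 'down' or None")
    q_cr = table[f"q_core_rim_{core_rim_axis}"]
    q_th = table[f"q_tumor_host_{tumor_host_axis}"]
    lfc_cr = table[f"lfc_core_rim_{core_rim_axis}"]
    lfc_th = table[f"lfc_tumor_host_{tumor_host_axis}"]
    keep = (q_cr <= fdr_threshold) & (q_th <= fdr_threshold)
    for axis, lfc in (("core_rim", lfc_cr), ("tumor_host", lfc_th)):
        d = directions.get(axis)
        if d == "up":
            keep &= lfc > 0
        elif d == "down":
            keep &= lfc < 0

    def signed(axis: str, lfc: pd.Series) -> pd.Series:
        d = directions.get(axis)
        return -lfc if d == "down" else (lfc if d == "up" else lfc.abs())

    rank = (signed("core_rim", lfc_cr) + signed("tumor_host", lfc_th))[keep]
    members = list(rank.sort_values(ascending=False).index)
    return GeneSet(
        name,
        members,
        {
            "fdr_threshold": fdr_threshold,
            "core_rim_axis": core_rim_axis,
            "tumor_host_axis": tumor_host_axis,
            "directions": directions,
        },
    )


def gene_fold_summary(
    table: pd.DataFrame,
    gene_id: str,
    core_rim_axis: str = "graft",
    tumor_host_axis: str = "core",
) -> dict:
    """Linear-scale folds and q-values for one gene.

    Headline folds: tumor:host evaluated in the core compartment and
    core:rim in the graft (tumor-derived) transcriptome — the natural axes
    for a tumor-specific core-enriched factor. All four contrasts and the
    group means are included.
    """
    if gene_id not in table.index:
        raise KeyError(f"gene {gene_id!r} not present in enrichment table")
    row = table.loc[gene_id]
    out = {
        "gene": gene_id,
        "fold_tumor_host": float(2 ** row[f"lfc_tumor_host_{tumor_host_axis}"]),
        "fold_core_rim": float(2 ** row[f"lfc_core_rim_{core_rim_axis}"]),
        "q_tumor_host": float(row[f"q_tumor_host_{tumor_host_axis}"]),
        "q_core_rim": float(row[f"q_core_rim_{core_rim_axis}"]),
    }
    for c in CONTRASTS:
        out[f"fold_{c}"] = float(2 ** row[f"lfc_{c}"])
    for col in row.index:
        if col.startswith("mean_"):
            out[col] = float(row[col])
    return out


def gene_set_score(
    table: pd.DataFrame,
    gene_set: GeneSet,
    lfc_col: str = "lfc",
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Mean log2FC of a gene set with a size-matched permutation p-value.

    The p-value is the two-sided fraction of random same-size gene sets
    whose |mean log2FC| is at least the observed, with add-one smoothing.
    With ``n_permutations`` 0 only the score is returned (p absent).
    """
    overlap = table.index.intersection(pd.Index(gene_set.genes))
    if len(overlap) < 5:
        raise ValueError(
            f"gene set {gene_set.name!r} overlaps the table in only {len(overlap)} genes (need >= 5)"
        )
    lfc = table[lfc_col]
    score = float(lfc.loc[overlap].mean())
    result = {"score": score, "n_overlap": int(len(overlap)), "p_value": None}
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        values = lfc.to_numpy()
        perms = np.array(
            [
                values[rng.choice(len(values), size=len(overlap), replace=False)].mean()
                for _ in range(n_permutations)
            ]
        )
        result["p_value"] = float(
            (1 + int((np.abs(perms) >= abs(score)).sum())) / (n_permutations + 1)
        )
    return result


def fraction_increased(table: pd.DataFrame, gene_set: GeneSet, lfc_col: str = "lfc") -> float:
    """Fraction of set members with log2FC strictly above zero."""
    overlap = table.index.intersection(pd.Index(gene_set.genes))
    if len(overlap) == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the table")
    return float((table.loc[overlap, lfc_col] > 0).mean())


def write_enrichment_tsv(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(DIRECTION_HEADER + "\n")
        table.to_csv(fh, sep="\t")


def read_enrichment_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
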