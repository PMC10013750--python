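"""Shared in-memory containers and plain-text I/O.

Everything the pipeline exchanges between modules lives here: paired
graft/host transcript collections with their ortholog map, per-species
gene x sample count matrices with compartment/condition metadata, the
expression program that parameterizes the simulators, and the plasma
proteomics table. All on-disk formats are plain text (FASTA, FASTQ, TSV).
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPECIES = ("graft", "host")
COMPARTMENTS = ("core", "rim")


# ---------------------------------------------------------------------------
# transcriptomes


@dataclass
class OrthologTranscriptomes:
    """Paired graft/host transcript collections with a 1:1 ortholog map.

    Ortholog pairs are length-matched by construction; ``divergence`` is the
    per-base substitution probability used to derive each host sequence from
    its graft ortholog.
    """

    graft: dict[str, str]
    host: dict[str, str]
    ortholog_map: dict[str, str]  # host gene id -> graft gene id
    divergence: float = math.nan

    def __post_init__(self) -> None:
        if len(set(self.graft)) != len(self.graft) or len(set(self.host)) != len(self.host):
            raise ValueError("gene ids must be unique within each species")
        for h, g in self.ortholog_map.items():
            if h not in self.host or g not in self.graft:
                raise ValueError(f"ortholog pair ({h}, {g}) references unknown gene")
            if len(self.host[h]) != len(self.graft[g]):
                raise ValueError(f"ortholog pair ({h}, {g}) has mismatched lengths")

    @property
    def graft_of_host(self) -> dict[str, str]:
        return dict(self.ortholog_map)

    @property
    def host_of_graft(self) -> dict[str, str]:
        return {g: h for h, g in self.ortholog_map.items()}

    def mismatch_fraction(self, host_gene: str) -> float:
        """Observed pairwise mismatch fraction of one ortholog pair."""
        h = self.host[host_gene]
        g = self.graft[self.ortholog_map[host_gene]]
        return sum(a != b for a, b in zip(h, g)) / len(h)

    def write(self, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "graft_fasta": outdir / f"{prefix}graft.fa",
            "host_fasta": outdir / f"{prefix}host.fa",
            "ortholog_map": outdir / f"{prefix}orthologs.tsv",
        }
        write_fasta(self.graft, paths["graft_fasta"])
        write_fasta(self.host, paths["host_fasta"])
        pd.DataFrame(
            {"host_gene": list(self.ortholog_map), "graft_gene": list(self.ortholog_map.values())}
        ).to_csv(paths["ortholog_map"], sep="\t", index=False)
        return paths

    @classmethod
    def read(
        cls,
        graft_fasta: str | Path,
        host_fasta: str | Path,
        ortholog_map_tsv: str | Path,
        divergence: float = math.nan,
    ) -> "OrthologTranscriptomes":
        omap = pd.read_csv(ortholog_map_tsv, sep="\t")
        return cls(
            graft=read_fasta(graft_fasta),
            host=read_fasta(host_fasta),
            ortholog_map=dict(zip(omap["host_gene"], omap["graft_gene"])),
            divergence=divergence,
        )


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: pd.DataFrame, path: str | Path) -> None:
    """Write reads (columns ``read_id``, ``sequence``) with flat Q40 qualities."""
    with open(path, "w") as fh:
        for rid, seq in zip(reads["read_id"], reads["sequence"]):
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> pd.DataFrame:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    return pd.DataFrame({"read_id": ids, "sequence": seqs})


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class SpeciesCountMatrix:
    """Gene x sample integer counts for one species-of-origin.

    ``sample_meta`` is indexed by sample id with at least ``compartment``
    (core|rim) and ``condition`` columns.
    """

    counts: pd.DataFrame
    species: str
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("sample metadata must cover exactly the count columns, in order")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def select(self, compartment: str | None = None, condition: str | None = None) -> "SpeciesCountMatrix":
        keep = pd.Series(True, index=self.sample_meta.index)
        if compartment is not None:
            keep &= self.sample_meta["compartment"] == compartment
        if condition is not None:
            keep &= self.sample_meta["condition"] == condition
        cols = self.sample_meta.index[keep]
        return SpeciesCountMatrix(self.counts[cols], self.species, self.sample_meta.loc[cols])

    def write_tsv(self, path: str | Path) -> None:
        """TSV with a 2-line metadata header (compartment, condition)."""
        with open(path, "w") as fh:
            fh.write("#compartment\t" + "\t".join(self.sample_meta["compartment"]) + "\n")
            fh.write("#condition\t" + "\t".join(self.sample_meta["condition"]) + "\n")
            self.counts.rename_axis("gene").to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, species: str) -> "SpeciesCountMatrix":
        with open(path) as fh:
            comp = fh.readline().rstrip("\n").split("\t")[1:]
            cond = fh.readline().rstrip("\n").split("\t")[1:]
            counts = pd.read_csv(fh, sep="\t", index_col=0)
        meta = pd.DataFrame({"compartment": comp, "condition": cond}, index=counts.columns)
        return cls(counts, species, meta)


def concat_matrices(a: SpeciesCountMatrix, b: SpeciesCountMatrix) -> SpeciesCountMatrix:
    """Column-wise concatenation of two matrices of the same species."""
    if a.species != b.species:
        raise ValueError("cannot concatenate matrices of different species")
    counts = pd.concat([a.counts, b.counts], axis=1)
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids after concatenation")
    return SpeciesCountMatrix(counts, a.species, pd.concat([a.sample_meta, b.sample_meta]))


# ---------------------------------------------------------------------------
# expression program


@dataclass
class ExpressionProgram:
    """Mean expected counts per (gene, species, compartment), NB dispersion,
    and the per-compartment graft read fraction.

    ``means`` has genes on the index and a (species, compartment) MultiIndex
    on the columns. ``dispersion`` is the negative-binomial phi shared across
    genes (variance = mu + phi * mu^2; phi = 0 is Poisson).
    """

    means: pd.DataFrame
    dispersion: float
    graft_fraction: dict[str, float]

    def __post_init__(self) -> None:
        if self.means.empty:
            raise ValueError("expression program has no genes")
        if self.dispersion < 0:
            raise ValueError("negative-binomial dispersion must be >= 0")
        arr = np.asarray(self.means, float)
        if (arr < 0).any() or not np.isfinite(arr).all():
            raise ValueError("means must be finite and non-negative")
        for sp in SPECIES:
            for comp in COMPARTMENTS:
                if self.means[(sp, comp)].sum() <= 0:
                    raise ValueError(f"means for ({sp}, {comp}) sum to zero")
        for comp, f in self.graft_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"graft_fraction[{comp!r}]={f} outside [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.means.index


def default_program(
    genes: list[str] | pd.Index,
    marker_gene: str | None = None,
    *,
    marker_means: tuple[float, float, float, float] = (320.0, 20.0, 10.0, 10.0),
    graft_fraction: dict[str, float] | None = None,
    dispersion: float = 0.1,
    baseline_log_mean: float = math.log(30.0),
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionProgram:
    """Expression program emulating the xenograft study conditions.

    Baseline genes share one lognormal mean across species and compartments
    (null genes). The optional marker gene is planted at the enrichment of
    the study's perinecrotic factor: graft core/rim means 320/20 (16-fold
    core:rim) against host 10/10 (32-fold tumor:host in the core). Graft
    read fractions default to 0.84 (core) and 0.76 (rim).
    """
    genes = pd.Index(genes)
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=len(genes)))
    cols = pd.MultiIndex.from_product([SPECIES, COMPARTMENTS], names=["species", "compartment"])
    means = pd.DataFrame(np.tile(base[:, None], (1, 4)), index=genes, columns=cols)
    if marker_gene is not None:
        if marker_gene not in genes:
            raise ValueError(f"marker gene {marker_gene!r} not in gene list")
        gc, gr, hc, hr = marker_means
        means.loc[marker_gene] = [gc, gr, hc, hr]
    if graft_fraction is None:
        graft_fraction = {"core": 0.84, "rim": 0.76}
    return ExpressionProgram(means, dispersion, dict(graft_fraction))


def remove_core_program(prog: ExpressionProgram, genes: list[str]) -> ExpressionProgram:
    """Return a program with the core/rim difference removed for ``genes``.

    Models a knockdown condition in which the core-enrichment of those genes
    is abolished: their core means are set equal to their rim means in both
    species.
    """
    means = prog.means.copy()
    present = means.index.intersection(pd.Index(genes))
    for sp in SPECIES:
        means.loc[present, (sp, "core")] = means.loc[present, (sp, "rim")].to_numpy()
    return ExpressionProgram(means, prog.dispersion, dict(prog.graft_fraction))


# ---------------------------------------------------------------------------
# plasma proteomics


@dataclass
class PlasmaTable:
    """Protein x sample log2 abundances with per-sample labels.

    ``sample_meta`` is indexed by sample id; grouped analyses use a
    ``ctc_state`` column (high|low), paired analyses use ``subject`` and
    ``timepoint`` (early|late) columns.
    """

    abundance: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundance.columns.equals(self.sample_meta.index):
            raise ValueError("sample metadata must cover exactly the abundance columns, in order")
        if self.sample_meta.isna().any().any():
            raise ValueError("sample labels must not be missing")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for col in self.sample_meta.columns:
                fh.write(f"#{col}\t" + "\t".join(map(str, self.sample_meta[col])) + "\n")
            self.abundance.rename_axis("protein").to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PlasmaTable":
        header: dict[str, list[str]] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                fields = line.rstrip("\n").split("\t")
                header[fields[0][1:]] = fields[1:]
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            abundance = pd.read_csv(fh, sep="\t", index_col=0)
        meta = pd.DataFrame(header, index=abundance.columns)
        return cls(abundance, meta)
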