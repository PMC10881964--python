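"""Reading, validation, filtering and normalization of lineage count tables.

A *lineage* is the clonal descendant of a single transposon insertion event,
identified by its genomic insertion coordinate ``(contig, position, strand)``.
The raw observable is a lineage x sample matrix of read counts ``R[l, s]``;
all downstream inference works with plug-in frequency estimates
``f[l, s] = R[l, s] / D[s]`` where ``D[s]`` is the total coverage of sample
``s`` summed over the retained lineages.

Lineages falling within (or just upstream of) genes with known knockout
fitness effects ("fitness determinants") are removed before analysis, and
depths are re-summed over the retained set, so that relative fitnesses are
measured against the quasi-neutral remainder of the library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["host_id", "day", "condition", "kind", "species_library"]
SAMPLE_KINDS = {"input_technical_replicate", "fecal", "invitro"}

INPUT_KIND = "input_technical_replicate"


class CountTableError(ValueError):
    """Raised when a count table or its metadata violates an invariant."""


def lineage_id(contig: str, position: int, strand: str) -> str:
    return f"{contig}:{position}:{strand}"


@dataclass
class CountTable:
    """Lineage x sample read-count matrix with sample metadata.

    Attributes
    ----------
    counts
        Non-negative integer DataFrame; index = lineage ids, columns = sample ids.
    lineages
        Per-lineage coordinates (``contig``, ``position``, ``strand``),
        indexed like ``counts``.
    samples
        Per-sample metadata (``host_id``, ``day``, ``condition``, ``kind``,
        ``species_library``), indexed by sample id.
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame
    samples: pd.DataFrame

    @property
    def depths(self) -> pd.Series:
        """Total coverage D[s] per sample (column sums over retained lineages)."""
        return self.counts.sum(axis=0)

    @property
    def n_lineages(self) -> int:
        return self.counts.shape[0]

    def validate(self) -> "CountTable":
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate lineage ids: {dups[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise CountTableError("negative read counts present")
        missing = self.counts.columns.difference(self.samples.index)
        if len(missing):
            raise CountTableError(f"samples without metadata: {list(missing)}")
        zero = self.depths[self.depths <= 0]
        if len(zero):
            raise CountTableError(f"zero-depth sample(s): {list(zero.index)}")
        bad_kind = set(self.samples["kind"]) - SAMPLE_KINDS
        if bad_kind:
            raise CountTableError(f"unknown sample kind(s): {sorted(bad_kind)}")
        inp = self.samples[self.samples["kind"] == INPUT_KIND]
        if (inp["day"] != 0).any():
            raise CountTableError("input technical replicates must have day=0")
        return self

    def select_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        return CountTable(self.counts[sample_ids], self.lineages, self.samples.loc[sample_ids])

    def select_lineages(self, ids) -> "CountTable":
        ids = list(ids)
        return CountTable(self.counts.loc[ids], self.lineages.loc[ids], self.samples)


@dataclass
class GeneAnnotation:
    """A gene interval (1-based, inclusive) with a fitness-determinant flag."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    fitness_determinant: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class CohortPooledFrequencies:
    """Read-sum pooled frequencies over a cohort of hosts at one timepoint.

    Pooling is done on reads, not on per-sample frequencies: the pooled
    frequency is (sum of the lineage's reads over the cohort) / (sum of all
    reads over the cohort), which weights each replicate by its depth.
    """

    hosts: frozenset
    day: float
    freqs: pd.Series
    depth: int
    sample_ids: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# I/O


def load_count_table(counts_path, metadata_path) -> CountTable:
    """Load and validate a count table (TSV) plus its sample metadata (TSV).

    The counts file carries columns ``contig``, ``position``, ``strand``
    followed by one integer column per sample id; the metadata file carries
    one row per sample with the ``SampleRecord`` fields.
    """
    raw = pd.read_csv(counts_path, sep="\t")
    for col in ("contig", "position", "strand"):
        if col not in raw.columns:
            raise CountTableError(f"counts file missing column {col!r}")
    meta = pd.read_csv(metadata_path, sep="\t").set_index("sample_id")
    ids = [lineage_id(c, p, s) for c, p, s in zip(raw["contig"], raw["position"], raw["strand"])]
    lineages = pd.DataFrame(
        {"contig": raw["contig"].to_numpy(), "position": raw["position"].to_numpy(),
         "strand": raw["strand"].to_numpy()},
        index=pd.Index(ids, name="lineage_id"),
    )
    sample_cols = [c for c in raw.columns if c not in ("contig", "position", "strand")]
    counts = raw[sample_cols].copy()
    counts.index = lineages.index
    if not all(np.issubdtype(dt, np.number) for dt in counts.dtypes):
        raise CountTableError("non-numeric count column")
    counts = counts.astype(np.int64)
    return CountTable(counts, lineages, meta).validate()


def save_count_table(table: CountTable, counts_path, metadata_path=None) -> None:
    out = pd.concat([table.lineages, table.counts], axis=1)
    out.to_csv(counts_path, sep="\t", index=False)
    if metadata_path is not None:
        table.samples.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def load_annotations(path, determinants_path=None) -> list[GeneAnnotation]:
    """Load gene annotations from a TSV (gene_id, contig, start, end, strand
    [, fitness_determinant]) or a genes-only GFF3 file.

    ``determinants_path`` optionally names a one-gene-id-per-line file whose
    entries are flagged as fitness determinants.
    """
    path = Path(path)
    flagged = set()
    if determinants_path is not None:
        flagged = {ln.strip() for ln in Path(determinants_path).read_text().splitlines() if ln.strip()}
    genes = []
    if path.suffix.lower() in {".gff", ".gff3"}:
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}-{f[4]}"))
            genes.append(GeneAnnotation(gid, f[0], int(f[3]), int(f[4]), f[6], gid in flagged))
    else:
        df = pd.read_csv(path, sep="\t")
        has_flag = "fitness_determinant" in df.columns
        for row in df.itertuples(index=False):
            fd = bool(getattr(row, "fitness_determinant")) if has_flag else row.gene_id in flagged
            genes.append(GeneAnnotation(row.gene_id, row.contig, int(row.start), int(row.end),
                                        row.strand, fd or row.gene_id in flagged))
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise CountTableError(f"duplicate gene id {g.gene_id}")
        seen.add(g.gene_id)
    return genes


# ---------------------------------------------------------------------------
# Gene assignment and filtering


def assign_lineages_to_genes(table: CountTable, genes, upstream_bp: int = 100,
                             inclusive_boundary: bool = False) -> pd.Series:
    """Map each insertion to at most one gene.

    An insertion maps to a gene if it lies inside the (1-based, inclusive)
    coding interval, or within ``upstream_bp`` of the strand-aware gene start
    (before ``start`` for +, after ``end`` for -).  With
    ``inclusive_boundary=False`` the upstream window is the open interval
    ``0 < distance < upstream_bp``; with ``True`` the boundary base
    ``distance == upstream_bp`` is also accepted.  If several genes claim one
    insertion the gene whose start coordinate is nearest wins (ties by gene
    id); the ambiguity is logged.

    Returns a Series indexed by lineage id with gene ids (NaN = unassigned).
    """
    pad = upstream_bp if inclusive_boundary else upstream_bp - 1
    trees: dict[str, IntervalTree] = {}
    by_id = {g.gene_id: g for g in genes}
    for g in genes:
        lo = g.start - pad if g.strand == "+" else g.start
        hi = g.end if g.strand == "+" else g.end + pad
        # IntervalTree intervals are half-open [begin, end)
        trees.setdefault(g.contig, IntervalTree()).addi(lo, hi + 1, g.gene_id)

    out = pd.Series(np.nan, index=table.lineages.index, dtype=object)
    n_ambiguous = 0
    for lid, contig, pos in zip(table.lineages.index, table.lineages["contig"],
                                table.lineages["position"]):
        tree = trees.get(contig)
        if tree is None:
            continue
        hits = tree[pos]
        if not hits:
            continue
        if len(hits) > 1:
            n_ambiguous += 1
        gid = min(
            (iv.data for iv in hits),
            key=lambda g: (abs(by_id[g].start - pos), g),
        )
        out[lid] = gid
    if n_ambiguous:
        logger.info("assign_lineages_to_genes: %d insertions claimed by >1 gene "
                    "(nearest-start tie-break applied)", n_ambiguous)
    return out


def filter_fitness_determinants(table: CountTable, genes, upstream_bp: int = 100) -> CountTable:
    """Drop lineages inside or <=``upstream_bp`` upstream of a fitness-determinant
    gene and re-sum depths over the retained quasi-neutral set."""
    flagged = [g for g in genes if g.fitness_determinant]
    if not flagged:
        return table
    gene_map = assign_lineages_to_genes(table, flagged, upstream_bp=upstream_bp,
                                        inclusive_boundary=True)
    keep = gene_map.isna()
    if not keep.any():
        raise CountTableError("all lineages filtered: every insertion falls in a "
                              "fitness-determinant gene")
    logger.info("fitness-determinant filter: %d -> %d lineages",
                len(keep), int(keep.sum()))
    return CountTable(table.counts.loc[keep], table.lineages.loc[keep], table.samples)


# ---------------------------------------------------------------------------
# Frequencies


def estimate_frequencies(table: CountTable) -> pd.DataFrame:
    """Plug-in frequency estimates f[l, s] = R[l, s] / D[s]; columns sum to 1."""
    depths = table.depths
    if (depths <= 0).any():
        raise CountTableError("zero-depth sample")
    return table.counts / depths


def pool_samples(table: CountTable, sample_ids) -> CohortPooledFrequencies:
    """Read-sum pooling over an explicit sample list (used for splitting
    input technical replicates between cohorts)."""
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise CountTableError("empty sample list for pooling")
    sub = table.counts[sample_ids]
    reads = sub.sum(axis=1)
    depth = int(reads.sum())
    if depth <= 0:
        raise CountTableError(f"pooled depth is zero for samples {sample_ids}")
    hosts = frozenset(table.samples.loc[sample_ids, "host_id"])
    days = set(table.samples.loc[sample_ids, "day"])
    day = days.pop() if len(days) == 1 else float("nan")
    return CohortPooledFrequencies(hosts, day, reads / depth, depth, tuple(sample_ids))


def pool_cohort(table: CountTable, hosts, day, kind=None) -> CohortPooledFrequencies:
    """Pool the samples of a cohort of hosts at one timepoint by read sums.

    Hosts without a sample at the timepoint are skipped with a warning; an
    entirely empty cohort is an error.
    """
    hosts = set(hosts)
    if not hosts:
        raise CountTableError("empty cohort")
    meta = table.samples
    mask = meta["host_id"].isin(hosts) & (meta["day"] == day)
    if kind is not None:
        mask &= meta["kind"] == kind
    picked = meta.index[mask]
    got = set(meta.loc[picked, "host_id"])
    for h in hosts - got:
        logger.warning("pool_cohort: host %s has no sample at day %s; skipped", h, day)
    if not len(picked):
        raise CountTableError(f"no samples for cohort {sorted(hosts)} at day {day}")
    return pool_samples(table, picked)
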