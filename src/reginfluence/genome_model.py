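"""Domain types and genomic plumbing: TSS annotations, binding sites, and
site-to-gene association.

Coordinate conventions (used consistently everywhere in the package):

* Binding-site intervals are BED-style 0-based half-open on disk and in
  :class:`BindingSite`.
* TSS positions are 1-based single base positions.
* A site's position is its interval midpoint, ``floor((start + end) / 2)``
  in 0-based coordinates, reported 1-based (i.e. ``+ 1``).
* Signed distance from a site to a TSS is measured in the gene's direction
  of transcription: negative upstream, positive downstream.  On the minus
  strand the genomic sign flips.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TSSAnnotation",
    "BindingSite",
    "ProfileEntry",
    "GeneBindingProfile",
    "ExpressionTable",
    "read_tss_table",
    "write_tss_table",
    "read_sites_bed",
    "write_sites_bed",
    "read_expression_table",
    "write_expression_table",
    "define_regulatory_regions",
    "signed_distance",
    "associate_sites",
    "nearest_gene_assignment",
    "classify_proximal",
]

_VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class TSSAnnotation:
    """One transcript (or probe set) transcription start site.

    Each probe set is treated independently as a separate gene, so
    ``gene_id`` must be unique within an annotation set.
    """

    gene_id: str
    chrom: str
    tss_pos: int  # 1-based
    strand: str

    def __post_init__(self) -> None:
        if self.tss_pos < 1:
            raise ValueError(f"tss_pos must be >= 1, got {self.tss_pos}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class BindingSite:
    """A putative regulatory region in one tissue.

    ``start``/``end`` are 0-based half-open.  ``regulators`` is the set of
    proteins observed bound at the region (may be empty for plain BED3
    input); ``enrichment`` is a ChIP enrichment ratio and ``conservation``
    a score in [0, 1], both optional.
    """

    site_id: str
    chrom: str
    start: int
    end: int
    tissue: str
    regulators: frozenset[str] = frozenset()
    enrichment: float | None = None
    conservation: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"site {self.site_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.enrichment is not None and self.enrichment <= 0:
            raise ValueError(f"site {self.site_id}: enrichment must be > 0")
        if self.conservation is not None and not (0.0 <= self.conservation <= 1.0):
            raise ValueError(f"site {self.site_id}: conservation must be in [0, 1]")

    @property
    def midpoint(self) -> int:
        """Interval midpoint as a 1-based base position."""
        return (self.start + self.end) // 2 + 1


@dataclass(frozen=True)
class ProfileEntry:
    """One site associated with one gene: its signed distance and modifiers."""

    signed_distance: int
    site_id: str
    alpha: float = 1.0
    conservation: float | None = None
    regulators: frozenset[str] = frozenset()
    enrichment: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class GeneBindingProfile:
    """All sites associated with one gene in one tissue.

    An empty ``entries`` list means the gene is unbound at the cutoff the
    profile was built with; such genes are retained so that downstream
    steps can decide whether to keep them.
    """

    gene_id: str
    tissue: str
    entries: list[ProfileEntry] = field(default_factory=list)

    @property
    def bound(self) -> bool:
        return len(self.entries) > 0


@dataclass
class ExpressionTable:
    """Log expression per gene and tissue, with an optional differential flag.

    ``values`` is indexed by gene_id with one column per tissue; the index
    is unique and all values are finite.
    """

    values: pd.DataFrame
    differential: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_id in expression table: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression table contains non-finite values")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_tss_table(path) -> list[TSSAnnotation]:
    """Read a TSV with header columns gene_id, chrom, pos, strand."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "pos", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing required column(s): {sorted(missing)}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id in TSS table: {dup.iloc[0]!r}")
    out = []
    for row in df.itertuples(index=False):
        try:
            pos = int(row.pos)
        except ValueError as exc:
            raise ValueError(f"non-integer TSS position {row.pos!r} for {row.gene_id}") from exc
        out.append(TSSAnnotation(row.gene_id, row.chrom, pos, row.strand))
    return out


def write_tss_table(annotations: list[TSSAnnotation], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annotations],
            "chrom": [a.chrom for a in annotations],
            "pos": [a.tss_pos for a in annotations],
            "strand": [a.strand for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


_BED_MISSING = "."


def read_sites_bed(path, tissue: str) -> list[BindingSite]:
    """Read binding sites from BED3+ (whitespace separated, no header).

    Optional columns 4-7 are site_id, comma-separated regulators,
    enrichment ratio and conservation score; ``.`` marks an absent value.
    """
    sites: list[BindingSite] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected at least 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            start, end = int(start_s), int(end_s)
            site_id = fields[3] if len(fields) > 3 and fields[3] != _BED_MISSING else f"{chrom}:{start}-{end}"
            regulators: frozenset[str] = frozenset()
            if len(fields) > 4 and fields[4] != _BED_MISSING:
                regulators = frozenset(r for r in fields[4].split(",") if r)
            enrichment = None
            if len(fields) > 5 and fields[5] != _BED_MISSING:
                try:
                    enrichment = float(fields[5])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-numeric enrichment {fields[5]!r}") from exc
            conservation = None
            if len(fields) > 6 and fields[6] != _BED_MISSING:
                conservation = float(fields[6])
            try:
                sites.append(
                    BindingSite(site_id, chrom, start, end, tissue, regulators, enrichment, conservation)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return sites


def write_sites_bed(sites: list[BindingSite], path) -> None:
    """Write sites as BED7 (site_id, regulators, enrichment, conservation)."""
    with open(path, "w") as fh:
        for s in sites:
            regs = ",".join(sorted(s.regulators)) if s.regulators else _BED_MISSING
            enr = repr(s.enrichment) if s.enrichment is not None else _BED_MISSING
            cons = repr(s.conservation) if s.conservation is not None else _BED_MISSING
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\t{regs}\t{enr}\t{cons}\n")


def read_expression_table(path) -> ExpressionTable:
    """Read a TSV with gene_id plus one column per tissue.

    An optional boolean column named ``differential`` flags differentially
    expressed genes.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("expression table missing required column 'gene_id'")
    df = df.set_index("gene_id")
    differential = None
    if "differential" in df.columns:
        differential = df.pop("differential").astype(bool)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"NaN expression value for gene {bad!r}")
    return ExpressionTable(df.astype(float), differential)


def write_expression_table(table: ExpressionTable, path) -> None:
    df = table.values.copy()
    if table.differential is not None:
        df["differential"] = table.differential
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Regulatory-region definition
# ---------------------------------------------------------------------------

def define_regulatory_regions(
    peak_sets: dict[str, list[BindingSite]],
    p300_name: str | None = None,
) -> list[BindingSite]:
    """Merge per-regulator peak sets into putative regulatory regions.

    A region is retained when the maximal merged interval overlaps a peak
    of the designated coactivator (``p300_name``) or overlaps peaks from at
    least two distinct other regulators.  When ``p300_name`` is None, every
    merged interval is retained (single-coregulator mode, e.g. CBP-only
    promoter arrays).

    The output regulator set is the union of contributing regulators and
    the enrichment the maximum over contributing peaks.
    """
    if p300_name is not None and p300_name not in peak_sets:
        raise ValueError(f"unknown p300_name {p300_name!r}; known sets: {sorted(peak_sets)}")

    peaks: list[tuple[BindingSite, str]] = []
    for reg, plist in peak_sets.items():
        for p in plist:
            peaks.append((p, reg))
    peaks.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    regions: list[BindingSite] = []
    cluster: list[tuple[BindingSite, str]] = []

    def _flush() -> None:
        if not cluster:
            return
        regs_here = {reg for _, reg in cluster}
        keep = (
            p300_name is None
            or p300_name in regs_here
            or len(regs_here - {p300_name}) >= 2
        )
        if not keep:
            return
        start = min(p.start for p, _ in cluster)
        end = max(p.end for p, _ in cluster)
        site_regs = frozenset().union(*(p.regulators for p, _ in cluster)) | frozenset(regs_here)
        enrichments = [p.enrichment for p, _ in cluster if p.enrichment is not None]
        regions.append(
            BindingSite(
                site_id=f"region_{len(regions):05d}",
                chrom=cluster[0][0].chrom,
                start=start,
                end=end,
                tissue=cluster[0][0].tissue,
                regulators=site_regs,
                enrichment=max(enrichments) if enrichments else None,
            )
        )

    cur_chrom, cur_end = None, -1
    for p, reg in peaks:
        if p.chrom != cur_chrom or p.start >= cur_end:
            _flush()
            cluster = [(p, reg)]
            cur_chrom, cur_end = p.chrom, p.end
        else:
            cluster.append((p, reg))
            cur_end = max(cur_end, p.end)
    _flush()
    return regions


# ---------------------------------------------------------------------------
# Distances and association
# ---------------------------------------------------------------------------

def signed_distance(site: BindingSite, tss: TSSAnnotation) -> int:
    """Signed bp distance from site midpoint to the TSS.

    Negative means upstream of the TSS in the gene's transcription
    direction; on the minus strand the genomic sign flips.
    """
    if site.chrom != tss.chrom:
        raise ValueError(
            f"site {site.site_id} on {site.chrom} but TSS {tss.gene_id} on {tss.chrom}"
        )
    d = site.midpoint - tss.tss_pos
    return -d if tss.strand == "-" else d


def _entry_for(site: BindingSite, tss: TSSAnnotation) -> ProfileEntry:
    return ProfileEntry(
        signed_distance=signed_distance(site, tss),
        site_id=site.site_id,
        alpha=1.0,
        conservation=site.conservation,
        regulators=site.regulators,
        enrichment=site.enrichment,
    )


def _sites_by_chrom(sites: list[BindingSite]):
    by: dict[str, list[BindingSite]] = defaultdict(list)
    for s in sites:
        by[s.chrom].append(s)
    out = {}
    for chrom, ss in by.items():
        ss.sort(key=lambda s: (s.midpoint, s.site_id))
        out[chrom] = ([s.midpoint for s in ss], ss)
    return out


def _resolve_window(
    cutoff: int | None, window: tuple[int, int] | None
) -> tuple[int, int]:
    """A symmetric cutoff or an explicit signed (upstream, downstream) window."""
    if window is not None:
        w0, w1 = int(window[0]), int(window[1])
        if w0 >= w1:
            raise ValueError("window must satisfy upstream < downstream bound")
        return w0, w1
    if cutoff is None or cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return -cutoff, cutoff


def associate_sites(
    genes: list[TSSAnnotation],
    sites: list[BindingSite],
    cutoff: int | None = None,
    window: tuple[int, int] | None = None,
) -> list[GeneBindingProfile]:
    """Associate every site whose signed distance lies in the window.

    ``cutoff`` gives the symmetric window [-cutoff, +cutoff] (boundaries
    inclusive); alternatively an explicit signed ``window`` restricts the
    association asymmetrically in the transcription direction, e.g.
    (-5500, 2500) for promoter-array data.  A site may appear in many
    gene profiles; genes with no site in range get an empty profile
    (retained).
    """
    w0, w1 = _resolve_window(cutoff, window)
    index = _sites_by_chrom(sites)
    profiles = []
    for g in genes:
        entries: list[ProfileEntry] = []
        if g.chrom in index:
            mids, ss = index[g.chrom]
            # Signed window mapped to genomic coordinates by strand.
            glo, ghi = (g.tss_pos + w0, g.tss_pos + w1) if g.strand == "+" else (
                g.tss_pos - w1, g.tss_pos - w0)
            lo = bisect.bisect_left(mids, glo)
            hi = bisect.bisect_right(mids, ghi)
            entries = [_entry_for(s, g) for s in ss[lo:hi]]
            entries = [e for e in entries if w0 <= e.signed_distance <= w1]
            entries.sort(key=lambda e: (abs(e.signed_distance), e.site_id))
        tissue = sites[0].tissue if sites else ""
        profiles.append(GeneBindingProfile(g.gene_id, tissue, entries))
    return profiles


def nearest_gene_assignment(
    genes: list[TSSAnnotation],
    sites: list[BindingSite],
    cutoff: int | None = None,
    window: tuple[int, int] | None = None,
) -> list[GeneBindingProfile]:
    """As :func:`associate_sites`, but each site joins only its nearest gene.

    Ties on |distance| are broken by lexicographic gene_id so runs are
    reproducible.  Sites outside the window of every gene are dropped.
    """
    w0, w1 = _resolve_window(cutoff, window)
    genes_by_chrom: dict[str, list[TSSAnnotation]] = defaultdict(list)
    for g in genes:
        genes_by_chrom[g.chrom].append(g)
    for gs in genes_by_chrom.values():
        gs.sort(key=lambda g: (g.tss_pos, g.gene_id))

    assigned: dict[str, list[ProfileEntry]] = defaultdict(list)
    for s in sites:
        candidates = genes_by_chrom.get(s.chrom, [])
        best: tuple[int, str] | None = None
        best_gene = None
        for g in candidates:
            d = signed_distance(s, g)
            if not (w0 <= d <= w1):
                continue
            key = (abs(d), g.gene_id)
            if best is None or key < best:
                best, best_gene = key, g
        if best_gene is not None:
            assigned[best_gene.gene_id].append(_entry_for(s, best_gene))

    tissue = sites[0].tissue if sites else ""
    profiles = []
    for g in genes:
        entries = sorted(assigned.get(g.gene_id, []), key=lambda e: (abs(e.signed_distance), e.site_id))
        profiles.append(GeneBindingProfile(g.gene_id, tissue, entries))
    return profiles


def classify_proximal(
    site: BindingSite, genes: list[TSSAnnotation], half_window: int = 250
) -> bool:
    """True iff the site midpoint falls within ±half_window of any TSS."""
    mid = site.midpoint
    return any(
        g.chrom == site.chrom and abs(mid - g.tss_pos) <= half_window for g in genes
    )
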