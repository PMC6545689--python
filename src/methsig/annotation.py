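"""Probe annotation: CGI context, TSS context and gene assignment.

Every 450K probe interrogates a single CpG position. Probes are categorised
by their distance to the closest CpG island (CGI): ``Island`` inside a CGI,
``Shore`` within 2 kb of one, ``Shelf`` between 2 and 4 kb, ``OpenSea``
beyond 4 kb. The shore/shelf categories carry an ``N_``/``S_`` prefix naming
the flank of the CGI the probe sits on; by default ``N_`` means the nearest
CGI lies at higher genomic coordinates (the probe is on its lower-coordinate
side). Probes are also categorised relative to transcription start sites
(strand-aware): ``TSS200`` within 0-200 bases upstream of a TSS, ``TSS1500``
within 200-1500 bases upstream, ``FirstExon`` inside a first exon, ``Far``
otherwise, with priority FirstExon > TSS200 > TSS1500 > Far when several
transcripts apply.

Distances are measured in bases from the probe position to the nearest
covered base of the interval. "Within 2000" is read as d <= 2000 and the
shelf band as 2000 < d <= 4000 (closed upper bounds).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import IntervalSet

__all__ = [
    "CGI_CATEGORIES",
    "TSS_CATEGORIES",
    "categorize_cgi",
    "categorize_cgi_vector",
    "categorize_tss",
    "assign_gene",
    "annotate_manifest",
    "collapse_cgi_category",
]

CGI_CATEGORIES = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
TSS_CATEGORIES = ["FirstExon", "TSS200", "TSS1500", "Far"]
SHORE_MAX = 2000
SHELF_MAX = 4000

_TSS_PRIORITY = {"FirstExon": 0, "TSS200": 1, "TSS1500": 2, "Far": 3}


def collapse_cgi_category(category: str) -> str:
    """Collapse N_/S_ flank labels: N_Shore/S_Shore -> Shore etc."""
    return category.split("_", 1)[-1] if "_" in category else category


def categorize_cgi_vector(
    pos,
    cgis: IntervalSet,
    chrom: str,
    convention: str = "genomic",
) -> np.ndarray:
    """CGI-context category for an array of probe positions on one chromosome.

    Parameters
    ----------
    pos
        Probe positions (0-based) on ``chrom``.
    cgis
        CGI intervals. An empty set yields ``OpenSea`` for every probe.
    convention
        ``"genomic"`` (default): ``N_`` when the nearest CGI is at higher
        coordinates. ``"cgi_relative"`` swaps the two prefixes. The array
        vendor's own flank convention is not restated in our sources, so both
        are exposed.
    """
    if convention not in ("genomic", "cgi_relative"):
        raise ValueError(f"unknown convention {convention!r}")
    pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    if cgis.is_empty():
        return np.full(pos.shape, "OpenSea", dtype=object)
    if cgis.is_empty(chrom):
        raise KeyError(f"chromosome {chrom!r} absent from CGI set")
    dist, side = cgis.nearest_edge(chrom, pos)
    out = np.full(pos.shape, "OpenSea", dtype=object)
    out[dist == 0] = "Island"
    prefix_hi, prefix_lo = ("N_", "S_") if convention == "genomic" else ("S_", "N_")
    prefix = np.where(side > 0, prefix_hi, prefix_lo)
    shore = (dist > 0) & (dist <= SHORE_MAX)
    shelf = (dist > SHORE_MAX) & (dist <= SHELF_MAX)
    for mask, base in ((shore, "Shore"), (shelf, "Shelf")):
        if mask.any():
            out[mask] = np.char.add(prefix[mask].astype(str), base)
    return out


def categorize_cgi(pos: int, cgis: IntervalSet, chrom: str, convention: str = "genomic") -> str:
    """Scalar convenience wrapper around :func:`categorize_cgi_vector`."""
    return str(categorize_cgi_vector([pos], cgis, chrom, convention)[0])


def _tss_category_one(pos: int, tss: int, strand: str, fe_start: int, fe_end: int) -> str:
    if fe_start < fe_end and fe_start <= pos < fe_end:
        return "FirstExon"
    d = tss - pos if strand == "+" else pos - tss  # upstream distance, strand-aware
    if 0 <= d <= 200:
        return "TSS200"
    if 200 < d <= 1500:
        return "TSS1500"
    return "Far"


def categorize_tss(pos: int, transcripts) -> str:
    """TSS-context category with priority FirstExon > TSS200 > TSS1500 > Far.

    ``transcripts`` is an iterable of ``(tss, strand, first_exon_start,
    first_exon_end)`` tuples for transcripts on the probe's chromosome; an
    empty iterable yields ``Far``.
    """
    best = "Far"
    for tss, strand, fe_start, fe_end in transcripts:
        cat = _tss_category_one(pos, tss, strand, fe_start, fe_end)
        if _TSS_PRIORITY[cat] < _TSS_PRIORITY[best]:
            best = cat
        if best == "FirstExon":
            break
    return best


def assign_gene(pos: int, chrom: str, genes: pd.DataFrame, upstream: int = 1500) -> str | None:
    """Assign a probe to a gene by body-or-promoter containment.

    A gene's window is its body extended ``upstream`` bases past the TSS on
    the strand-appropriate side. Among containing genes the one whose body is
    nearest wins (distance 0 inside the body); remaining ties break to the
    lexicographically smaller gene id. Returns ``None`` when no window
    contains the probe. This is a deliberately simple probe->gene mapping,
    not a transcript-model annotator.
    """
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return None
    start = sub["start"].to_numpy(np.int64)
    end = sub["end"].to_numpy(np.int64)
    plus = (sub["strand"] == "+").to_numpy()
    wstart = np.where(plus, start - upstream, start)
    wend = np.where(plus, end, end + upstream)
    inside = (wstart <= pos) & (pos < wend)
    if not inside.any():
        return None
    body_dist = np.maximum(0, np.maximum(start - pos, pos - (end - 1)))
    ids = sub["gene_id"].to_numpy(object)
    cand = np.flatnonzero(inside)
    order = sorted(cand, key=lambda i: (body_dist[i], str(ids[i])))
    return str(ids[order[0]])


def annotate_manifest(
    manifest: pd.DataFrame,
    cgis: IntervalSet,
    genes: pd.DataFrame | None = None,
    convention: str = "genomic",
) -> pd.DataFrame:
    """Attach cgi_category/cgi_group/tss_category/gene columns to a manifest.

    Negative-control probes (``is_negative_control``) have no genomic context
    and receive empty annotations. ``genes`` needs columns ``gene_id, chrom,
    start, end, strand, tss, first_exon_start, first_exon_end``.
    """
    out = manifest.copy()
    ctrl = out.get("is_negative_control", pd.Series(False, index=out.index)).astype(bool)
    out["cgi_category"] = ""
    out["tss_category"] = ""
    out["gene"] = ""
    target = ~ctrl
    for chrom, sub in out[target].groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        if cgis.is_empty() or cgis.is_empty(str(chrom)):
            cats = np.full(len(sub), "OpenSea", dtype=object)
        else:
            cats = categorize_cgi_vector(pos, cgis, str(chrom), convention)
        out.loc[sub.index, "cgi_category"] = cats
        if genes is not None:
            gsub = genes[genes["chrom"] == chrom]
            transcripts = list(
                zip(gsub["tss"], gsub["strand"], gsub["first_exon_start"], gsub["first_exon_end"])
            )
            out.loc[sub.index, "tss_category"] = [categorize_tss(p, transcripts) for p in pos]
            out.loc[sub.index, "gene"] = [
                assign_gene(p, str(chrom), genes) or "" for p in pos
            ]
        else:
            out.loc[sub.index, "tss_category"] = "Far"
    out["cgi_group"] = [collapse_cgi_category(c) if c else "" for c in out["cgi_category"]]
    return out
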