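"""Compositional preprocessing of amplicon count tables.

Prevalence/abundance filtering, per-marker centered log-ratio transform,
domain subsetting for the five network variants (BAF / BA / BF / B / F), and
discretization of the methane profile into the binary high/low response used
by balance selection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ClrMatrix, CountTable, EmptyResultError, SampleMetadata

log = logging.getLogger(__name__)

#: default SMTZ depth interval (cm below sea floor)
SMTZ_INTERVAL_CM = (10.0, 13.0)


def filter_taxa(
    counts: CountTable,
    min_prevalence: float = 0.30,
    min_mean_relabund: float = 1e-4,
    abundance_stat: str = "mean",
) -> CountTable:
    """Remove rare taxa before network construction.

    A taxon is retained when it is present (count > 0) in at least
    ``min_prevalence`` of samples AND its relative abundance (mean across
    samples by default; ``abundance_stat="max"`` for the permissive reading)
    is at least ``min_mean_relabund``.  Samples are never removed.
    """
    if counts.n_taxa == 0 or counts.n_samples == 0:
        raise EmptyResultError("empty count table")
    if abundance_stat not in ("mean", "max"):
        raise ValueError("abundance_stat must be 'mean' or 'max'")
    mat = counts.counts.to_numpy(dtype=float)
    prevalence = (mat > 0).mean(axis=0)
    totals = mat.sum(axis=1, keepdims=True)
    relabund = np.divide(mat, totals, out=np.zeros_like(mat), where=totals > 0)
    abund = relabund.mean(axis=0) if abundance_stat == "mean" else relabund.max(axis=0)
    keep = (prevalence >= min_prevalence) & (abund >= min_mean_relabund)
    kept = [t for t, k in zip(counts.taxon_ids, keep) if k]
    log.info("filter_taxa: retained %d of %d taxa", len(kept), counts.n_taxa)
    if not kept:
        raise EmptyResultError("all taxa removed by prevalence/abundance filter")
    return counts.subset_taxa(kept)


def clr_transform(counts: CountTable, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform, applied per marker block.

    Within each marker's taxa (16S and 18S libraries are closed separately):
    x -> ln(x + pseudocount) − mean over the block's taxa, per sample.  Rows
    of each block therefore sum to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    markers = sorted({counts.marker_of[t] for t in counts.taxon_ids})
    blocks: dict[str, list[str]] = {}
    out = pd.DataFrame(index=counts.counts.index, dtype=float)
    for marker in markers:
        taxa = [t for t in counts.taxon_ids if counts.marker_of[t] == marker]
        if not taxa:
            raise EmptyResultError(f"empty marker block {marker}")
        logx = np.log(counts.counts[taxa].to_numpy(dtype=float) + pseudocount)
        logx -= logx.mean(axis=1, keepdims=True)
        out[taxa] = logx
        blocks[marker] = taxa
    out = out[counts.taxon_ids]  # preserve original column order
    return ClrMatrix(
        values=out,
        pseudocount=float(pseudocount),
        marker_blocks=blocks,
        domain_of=dict(counts.domain_of),
        marker_of=dict(counts.marker_of),
        taxonomy=dict(counts.taxonomy),
    )


DOMAIN_VARIANTS = {
    "BAF": {"bacteria", "archaea", "fungus"},
    "BA": {"bacteria", "archaea"},
    "BF": {"bacteria", "fungus"},
    "B": {"bacteria"},
    "F": {"fungus"},
}


def subset_domains(counts: CountTable, domains: set[str] | list[str]) -> CountTable:
    """Keep only taxa whose domain is in ``domains`` (samples unchanged)."""
    domains = set(domains)
    if not domains:
        raise ValueError("domains must be non-empty")
    kept = [t for t in counts.taxon_ids if counts.domain_of[t] in domains]
    if not kept:
        raise EmptyResultError(f"no taxa with domain in {sorted(domains)}")
    return counts.subset_taxa(kept)


def discretize_methane(
    meta: SampleMetadata,
    smtz_interval_cm: tuple[float, float] = SMTZ_INTERVAL_CM,
    mode: str = "by_depth",
) -> pd.Series:
    """Label each sample "high" or "low" methane.

    ``by_depth``: high iff the sample's depth slice overlaps the SMTZ
    interval (the depth band where methane and methanotrophic activity peak).
    ``by_concentration``: high iff the measured methane exceeds the mean of
    the site's surface (shallowest) slice.  The returned Series carries the
    rule used in ``attrs``.
    """
    table = meta.table
    if mode == "by_depth":
        lo, hi = smtz_interval_cm
        top = table["depth_top_cm"].to_numpy(float)
        bottom = table["depth_bottom_cm"].to_numpy(float)
        high = (top < hi) & (bottom > lo)  # positive-measure overlap
    elif mode == "by_concentration":
        if "methane" not in table.columns or table["methane"].isna().all():
            raise ValueError("by_concentration requires methane measurements")
        high = np.zeros(len(table), dtype=bool)
        for site, grp in table.groupby("site"):
            surface_top = grp["depth_top_cm"].min()
            surface = grp[grp["depth_top_cm"] == surface_top]
            ref = surface["methane"].mean()
            mask = table["site"] == site
            high |= (mask & (table["methane"] > ref)).to_numpy()
    else:
        raise ValueError("mode must be 'by_depth' or 'by_concentration'")
    labels = pd.Series(np.where(high, "high", "low"), index=table.index,
                       name="methane_class")
    labels.attrs["mode"] = mode
    labels.attrs["smtz_interval_cm"] = list(smtz_interval_cm)
    return labels
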