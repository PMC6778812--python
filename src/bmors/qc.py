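"""Marker quality control and the genomic relationship matrix.

The filters mirror standard breeding-data pipelines: per-marker missingness,
minor allele frequency (MAF, removal at <= threshold) and heterozygosity.
All three criteria are computed on the original calls — the filters are
independent passes — but a marker is attributed to the first rule that hits
it, in the fixed order missingness -> MAF -> heterozygosity.

The kernel is G = W W' / p with W the (optionally column-centered) dosage
matrix and p the number of markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenomicRelationship, MarkerMatrix

__all__ = ["QCThresholds", "filter_markers", "impute_markers", "compute_grm"]


@dataclass
class QCThresholds:
    """Per-dataset marker filter settings.

    max_missing_frac : remove markers with missingness strictly above this.
    min_maf : remove markers with MAF <= this (note the inclusive rule).
    max_het_frac : remove markers with heterozygote fraction strictly above
        this; None disables the heterozygosity filter.
    """

    max_missing_frac: float = 0.8
    min_maf: float = 0.05
    max_het_frac: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.max_het_frac is not None and not 0.0 <= self.max_het_frac <= 1.0:
            raise ValueError("max_het_frac must be in [0, 1] or None")


def marker_stats(markers: MarkerMatrix) -> pd.DataFrame:
    """Per-marker missingness, MAF and heterozygosity on the original calls."""
    d = markers.dosages
    missing = np.isnan(d)
    n_called = (~missing).sum(axis=0)
    miss_frac = missing.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p_hat = np.nanmean(d, axis=0) / 2.0
        maf = np.minimum(p_hat, 1.0 - p_hat)
        het = np.where(n_called > 0, np.nansum(d == 1.0, axis=0) / n_called, np.nan)
    return pd.DataFrame({
        "marker": markers.marker_ids,
        "missing_frac": miss_frac,
        "maf": maf,
        "het_frac": het,
    })


def filter_markers(markers: MarkerMatrix, thresholds: QCThresholds):
    """Apply the QC filters; returns (filtered MarkerMatrix, removal log).

    The removal log has one row per removed marker with the rule that
    removed it.  Raises if no markers survive.
    """
    if markers.n_markers == 0:
        raise ValueError("empty marker matrix")
    stats = marker_stats(markers)
    rule = np.full(markers.n_markers, "", dtype=object)
    miss = stats["missing_frac"].to_numpy() > thresholds.max_missing_frac
    rule[miss] = "missingness"
    maf_hit = (stats["maf"].to_numpy() <= thresholds.min_maf) | np.isnan(
        stats["maf"].to_numpy()
    )
    rule[(rule == "") & maf_hit] = "maf"
    if thresholds.max_het_frac is not None:
        het_hit = stats["het_frac"].to_numpy() > thresholds.max_het_frac
        rule[(rule == "") & het_hit] = "heterozygosity"
    keep = rule == ""
    if not keep.any():
        raise ValueError("no markers survive QC")
    log = stats.loc[~keep].copy()
    log["rule"] = rule[~keep]
    kept = MarkerMatrix(
        markers.line_ids,
        [m for m, k in zip(markers.marker_ids, keep) if k],
        markers.dosages[:, keep],
    )
    return kept, log.reset_index(drop=True)


def impute_markers(markers: MarkerMatrix, method: str = "column_mean") -> MarkerMatrix:
    """Replace missing dosages by the per-marker mean of the non-missing calls."""
    if method != "column_mean":
        raise ValueError(f"unknown imputation method {method!r}")
    d = markers.dosages.copy()
    missing = np.isnan(d)
    if missing.all(axis=0).any():
        k = int(np.flatnonzero(missing.all(axis=0))[0])
        raise ValueError(
            f"marker {markers.marker_ids[k]!r} has no non-missing calls; "
            "it should have been removed by QC"
        )
    if missing.any():
        col_mean = np.nanmean(d, axis=0)
        d[missing] = np.broadcast_to(col_mean, d.shape)[missing]
    return MarkerMatrix(markers.line_ids, markers.marker_ids, d)


def compute_grm(markers: MarkerMatrix, center: bool = True) -> GenomicRelationship:
    """Genomic relationship matrix G = W W' / p.

    With ``center`` (default) each marker column of the dosage matrix is
    reduced by its mean before the cross-product, so G does not depend on
    which allele is counted.  ``center=False`` uses the raw 0/1/2 coding.
    """
    if markers.n_markers == 0:
        raise ValueError("cannot compute a GRM from zero markers")
    if np.isnan(markers.dosages).any():
        raise ValueError("marker matrix has missing dosages; impute first")
    W = markers.dosages
    if center:
        W = W - W.mean(axis=0, keepdims=True)
    G = W @ W.T / markers.n_markers
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return GenomicRelationship(markers.line_ids, G)
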