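"""Transcriptomic point-of-departure derivation from gene-level BMDs.

Postfilters the per-gene benchmark doses (drop BMDU/BMDL ratios above 40,
BMDs above the highest tested concentration, and BMDs more than 10-fold below
the lowest tested nonzero concentration), then derives two summary PODs:

- tPOD(10th): the 10th percentile of the retained BMDs;
- tPOD(mode): the lowest mode of a Gaussian kernel density estimate of the
  retained BMDs on the log10(µM) axis.  Antimodes (density minima between
  modes) bound the first-mode gene cluster, the genes used for
  sensitive-pathway enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .synthetic_data import DoseDesign

__all__ = ["TPODReport", "postfilter", "tpod_percentile", "kde_modes",
           "derive_tpods", "BMDU_BMDL_CAP", "TPOD_FRACTION"]

#: postfilter cap on the BMDU/BMDL ratio
BMDU_BMDL_CAP = 40.0
#: percentile (as a fraction) defining tPOD(10th)
TPOD_FRACTION = 0.10
#: modes below this fraction of the peak density are discarded as grid noise
MODE_MIN_DENSITY = 0.05
#: minimum number of retained BMDs for mode detection
MIN_FOR_KDE = 5


def postfilter(records: pd.DataFrame, max_conc: float,
               min_nonzero_conc: float,
               ratio_cap: float = BMDU_BMDL_CAP) -> pd.DataFrame:
    """Keep records with bmdu/bmdl <= cap, bmd <= max_conc and
    bmd >= min_nonzero_conc / 10; failed/absent BMDs are dropped."""
    if not max_conc > min_nonzero_conc > 0:
        raise ValueError("need max_conc > min_nonzero_conc > 0")
    if len(records) == 0:
        return records.reset_index(drop=True)
    r = records
    finite = r["bmd"].notna() & r["bmdl"].notna() & r["bmdu"].notna()
    finite &= np.isfinite(r["bmd"]) & np.isfinite(r["bmdl"]) \
        & np.isfinite(r["bmdu"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = r["bmdu"] / r["bmdl"]
    keep = (finite
            & (ratio <= ratio_cap)
            & (r["bmd"] <= max_conc)
            & (r["bmd"] >= min_nonzero_conc / 10.0))
    return r[keep.fillna(False)].reset_index(drop=True)


def tpod_percentile(bmds, fraction: float = TPOD_FRACTION) -> float:
    """Linear-interpolation (type 7) quantile of the retained BMDs."""
    v = np.asarray(bmds, dtype=float)
    if v.size == 0:
        raise ValueError("no retained BMDs; tPOD undefined")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return float(np.quantile(v, fraction))  # numpy default = linear / type 7


def kde_modes(bmds, bandwidth="silverman", grid_size: int = 512):
    """Gaussian-KDE modes and antimodes of BMDs on the log10(µM) axis.

    The density is evaluated on a ``grid_size``-point grid spanning the data
    range extended by 3 bandwidths.  Modes are strict local maxima (plus grid
    endpoints that dominate their neighbor) with density at least 5% of the
    global maximum; antimodes are the density minima between consecutive
    retained modes.  Returns ``(modes, antimodes, grid, density)`` with mode
    and antimode locations in log10(µM), ascending.
    """
    v = np.log10(np.asarray(bmds, dtype=float))
    if v.size < MIN_FOR_KDE:
        raise ValueError(f"need >= {MIN_FOR_KDE} BMDs for mode detection")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        # degenerate: all values identical; a single mode at the value
        g = np.linspace(v[0] - 0.5, v[0] + 0.5, grid_size)
        dens = np.zeros(grid_size)
        dens[np.argmin(np.abs(g - v[0]))] = 1.0
        return np.array([v[0]]), np.array([]), g, dens

    if bandwidth == "silverman":
        kde = gaussian_kde(v, bw_method="silverman")
    elif bandwidth == "scott":
        kde = gaussian_kde(v, bw_method="scott")
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
        kde = gaussian_kde(v, bw_method=h / sd)
    h = kde.factor * sd
    g = np.linspace(v.min() - 3.0 * h, v.max() + 3.0 * h, grid_size)
    dens = kde(g)

    interior = np.nonzero((dens[1:-1] > dens[:-2])
                          & (dens[1:-1] > dens[2:]))[0] + 1
    peaks = list(interior)
    if dens[0] > dens[1]:
        peaks = [0] + peaks
    if dens[-1] > dens[-2]:
        peaks = peaks + [grid_size - 1]
    peaks = [i for i in sorted(peaks)
             if dens[i] >= MODE_MIN_DENSITY * dens.max()]

    antimodes = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        j = a + int(np.argmin(dens[a:b + 1]))
        antimodes.append(g[j])
    return np.asarray(g[peaks]), np.asarray(antimodes), g, dens


@dataclass
class TPODReport:
    """Postfiltered BMD distribution and the derived PODs."""

    n_input: int
    n_retained: int
    bmds: np.ndarray                      # retained BMDs, µM
    tpod_10th: float | None
    tpod_mode: float | None
    bandwidth: float | None
    modes_log10: np.ndarray
    antimodes_log10: np.ndarray
    first_mode_gene_ids: list = field(default_factory=list)
    unimodal: bool = False
    retained: pd.DataFrame = None

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "tpod_10th_uM": self.tpod_10th,
            "tpod_mode_uM": self.tpod_mode,
            "kde_bandwidth_log10": self.bandwidth,
            "modes_log10": list(map(float, self.modes_log10)),
            "antimodes_log10": list(map(float, self.antimodes_log10)),
            "unimodal": self.unimodal,
            "first_mode_genes": list(self.first_mode_gene_ids),
        }


def derive_tpods(records: pd.DataFrame, design: DoseDesign = None,
                 max_conc: float = None, min_nonzero_conc: float = None,
                 fraction: float = TPOD_FRACTION,
                 bandwidth="silverman",
                 ratio_cap: float = BMDU_BMDL_CAP) -> TPODReport:
    """Postfilter gene BMD records and assemble the tPOD report.

    ``tpod_mode`` is 10**(lowest mode location); the first-mode gene set is
    every retained gene with log10(bmd) below the first antimode, or all
    retained genes (flagged ``unimodal``) when the density has a single mode.
    With fewer than 5 retained BMDs, mode detection is skipped with a warning
    and ``tpod_mode`` is None.
    """
    if design is not None:
        max_conc = design.max_conc
        min_nonzero_conc = design.min_nonzero_conc
    if max_conc is None or min_nonzero_conc is None:
        raise ValueError("provide a design or explicit concentration limits")

    kept = postfilter(records, max_conc, min_nonzero_conc, ratio_cap)
    if len(kept) == 0:
        raise ValueError("no BMDs survive the postfilter; tPOD undefined")
    bmds = kept["bmd"].to_numpy(float)
    t10 = tpod_percentile(bmds, fraction)

    if len(kept) < MIN_FOR_KDE:
        warnings.warn("fewer than 5 retained BMDs; mode detection skipped",
                      stacklevel=2)
        return TPODReport(n_input=len(records), n_retained=len(kept),
                          bmds=bmds, tpod_10th=t10, tpod_mode=None,
                          bandwidth=None, modes_log10=np.array([]),
                          antimodes_log10=np.array([]),
                          first_mode_gene_ids=[], unimodal=False,
                          retained=kept)

    modes, antimodes, grid, dens = kde_modes(bmds, bandwidth)
    sd = float(np.std(np.log10(bmds), ddof=1))
    bw = None
    if sd > 0:
        if bandwidth in ("silverman", "scott"):
            bw = gaussian_kde(np.log10(bmds), bw_method=bandwidth).factor * sd
        else:
            bw = float(bandwidth)
    tpod_mode = float(10.0 ** modes[0])
    unimodal = len(modes) == 1
    if unimodal:
        first_genes = list(kept["gene_id"])
    else:
        first_genes = list(kept.loc[np.log10(bmds) < antimodes[0], "gene_id"])
    return TPODReport(n_input=len(records), n_retained=len(kept), bmds=bmds,
                      tpod_10th=t10, tpod_mode=tpod_mode, bandwidth=bw,
                      modes_log10=modes, antimodes_log10=antimodes,
                      first_mode_gene_ids=first_genes, unimodal=unimodal,
                      retained=kept)
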