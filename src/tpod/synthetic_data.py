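"""Synthetic dose-series RNA-seq data with known per-gene dose-response truth.

Emulates the design of an EC20-anchored larval exposure experiment: a vehicle
control plus a geometric (default 10-fold) dilution series ending at the EC20,
a small number of biological replicates per concentration, and gene-level
counts that are negative-binomially distributed around a per-gene baseline.
A configurable minority of genes carry monotone or sigmoidal dose-dependent
shifts in mean expression on the log2 scale; the generator records the exact
curve and the true benchmark dose per gene so recovery by the analysis stages
can be scored.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "DoseDesign",
    "ResponseCurve",
    "TruthTable",
    "CountMatrix",
    "make_design",
    "make_truth",
    "simulate_counts",
    "true_bmd_of",
    "log2_noise_sd",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Dose design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseDesign:
    """Concentration series and replicate layout of an exposure experiment.

    ``concentrations`` are in µM, strictly increasing, with exactly one zero
    (the carrier control) and the top concentration equal to ``anchor`` (the
    EC20 of the compound).  Each nonzero concentration equals the next higher
    one divided by ``dilution_factor``.
    """

    concentrations: tuple
    n_replicates: int
    anchor: float
    dilution_factor: float = 10.0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim != 1 or len(c) < 2:
            raise ValueError("need at least control and one concentration")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.count_nonzero(c == 0.0) != 1 or c[0] != 0.0:
            raise ValueError("exactly one zero (control) entry required, first")
        if not math.isclose(c[-1], self.anchor, rel_tol=1e-9):
            raise ValueError("top concentration must equal the anchor")
        nz = c[c > 0]
        for lo, hi in zip(nz[:-1], nz[1:]):
            if not math.isclose(hi / lo, self.dilution_factor, rel_tol=1e-6):
                raise ValueError("successive concentrations must differ by "
                                 "the dilution factor")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per concentration")
        object.__setattr__(self, "concentrations", tuple(float(x) for x in c))

    @property
    def max_conc(self) -> float:
        return self.concentrations[-1]

    @property
    def min_nonzero_conc(self) -> float:
        return next(c for c in self.concentrations if c > 0)

    @property
    def n_samples(self) -> int:
        return len(self.concentrations) * self.n_replicates

    def sample_sheet(self) -> pd.DataFrame:
        """One row per sample: sample_id, concentration_uM, replicate."""
        rows = []
        for ci, conc in enumerate(self.concentrations):
            for r in range(self.n_replicates):
                rows.append({
                    "sample_id": f"c{ci}_r{r + 1}",
                    "concentration_uM": conc,
                    "replicate": f"rep{r + 1}",
                })
        return pd.DataFrame(rows)


def make_design(anchor_uM: float, n_dilutions: int = 3,
                dilution_factor: float = 10.0,
                n_replicates: int = 3) -> DoseDesign:
    """Build the control + dilution-series design anchored at the EC20.

    Returns 0 plus ``n_dilutions + 1`` concentrations ending at ``anchor_uM``,
    successive pairs related by ``dilution_factor``.
    """
    if anchor_uM <= 0:
        raise ValueError("anchor concentration must be positive")
    if dilution_factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n_dilutions < 0:
        raise ValueError("n_dilutions must be >= 0")
    concs = [anchor_uM / dilution_factor ** k for k in range(n_dilutions, -1, -1)]
    return DoseDesign(concentrations=tuple([0.0] + concs),
                      n_replicates=n_replicates, anchor=anchor_uM,
                      dilution_factor=dilution_factor)


# ---------------------------------------------------------------------------
# Response curves (log2-expression shift as a function of concentration)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseCurve:
    """Dose-dependent shift of log2 mean expression relative to control.

    Supported shapes (all evaluate to 0 at concentration 0):

    - ``null``: no response.
    - ``linear``: ``slope * c``, optionally saturating at ``|cap|`` log2
      units (keeps simulated count means biologically bounded while the
      curve stays linear through the low-dose region).
    - ``hill``: ``amplitude * c**n / (k**n + c**n)``.
    - ``exp``: ``amplitude * (1 - exp(-rate * c))``.
    """

    shape: str
    params: dict = field(default_factory=dict)

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        p = self.params
        if self.shape == "null":
            return np.zeros_like(c)
        if self.shape == "linear":
            s = p["slope"] * c
            cap = p.get("cap")
            return np.clip(s, -cap, cap) if cap is not None else s
        if self.shape == "hill":
            k, n, amp = p["k"], p["n"], p["amplitude"]
            cn = np.power(c, n)
            return amp * cn / (k ** n + cn)
        if self.shape == "exp":
            return p["amplitude"] * (1.0 - np.exp(-p["rate"] * c))
        raise ValueError(f"unknown curve shape {self.shape!r}")

    def to_json(self) -> str:
        return json.dumps({"shape": self.shape, "params": self.params},
                          sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ResponseCurve":
        d = json.loads(s)
        return cls(shape=d["shape"], params=d["params"])


def true_bmd_of(curve, bmr: float, c_max: float = None) -> float | None:
    """Smallest positive concentration where |curve(c) - curve(0)| = bmr.

    Found by a log-spaced bracketing scan followed by a root search; returns
    ``None`` if the response never reaches ``bmr`` within ``10 * c_max``.
    A non-monotone curve with multiple crossings yields the smallest one,
    with a warning.
    """
    if bmr <= 0:
        raise ValueError("bmr must be positive")
    if c_max is None or c_max <= 0:
        raise ValueError("c_max (top of the search range) must be positive")
    hi = 10.0 * c_max
    grid = np.concatenate([[0.0], np.geomspace(hi * 1e-9, hi, 2048)])
    base = float(np.asarray(curve(0.0)))
    dev = np.abs(np.asarray(curve(grid)) - base) - bmr
    sign_change = np.nonzero((dev[:-1] < 0) & (dev[1:] >= 0))[0]
    if len(sign_change) == 0:
        return None
    if len(sign_change) > 1:
        warnings.warn("multiple BMR crossings; returning the smallest",
                      stacklevel=2)
    i = sign_change[0]
    lo, up = grid[i], grid[i + 1]
    if dev[i + 1] == 0:
        return float(up)
    f = lambda c: abs(float(np.asarray(curve(c))) - base) - bmr
    return float(brentq(f, lo, up, xtol=1e-12 * hi, rtol=1e-12))


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

def log2_noise_sd(baseline_mean, dispersion):
    """Delta-method SD of log2(count) given NB mean and dispersion.

    Var(count) = mu + phi * mu^2, so Var(log2 count) ~ (1/mu + phi) / ln2^2.
    """
    mu = np.asarray(baseline_mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    return np.sqrt(1.0 / mu + phi) / LN2


@dataclass
class TruthTable:
    """Per-gene simulated ground truth.

    Backed by a DataFrame with columns ``gene_id``, ``baseline_mean``,
    ``dispersion``, ``responsive``, ``curve_json``, ``true_bmd`` (µM; NaN
    for non-responsive genes).  ``bmr_log2`` records the benchmark response
    (log2 units) at which ``true_bmd`` was solved.
    """

    frame: pd.DataFrame
    bmr_log2: float

    def __post_init__(self):
        f = self.frame
        if (f["baseline_mean"] <= 0).any():
            raise ValueError("baseline_mean must be positive")
        if (f["dispersion"] < 0).any():
            raise ValueError("dispersion must be non-negative")
        resp = f["responsive"].astype(bool)
        has_bmd = f["true_bmd"].notna()
        if not (resp == has_bmd).all():
            raise ValueError("true_bmd must be present iff responsive")
        if f["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")

    def __len__(self):
        return len(self.frame)

    def curves(self) -> list:
        return [ResponseCurve.from_json(s) for s in self.frame["curve_json"]]

    def to_tsv(self, path) -> None:
        self.frame.assign(bmr_log2=self.bmr_log2).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        f = pd.read_csv(path, sep="\t")
        bmr = float(f.pop("bmr_log2").iloc[0])
        return cls(frame=f, bmr_log2=bmr)


def make_truth(n_genes: int, design: DoseDesign, seed: int,
               responsive_fraction: float = 0.10,
               baseline_log_mean: float = math.log(100.0),
               baseline_log_sd: float = 1.2,
               dispersion: float = 0.05,
               amplitude_range: tuple = (1.0, 3.0),
               bmd_log10_centers: tuple = None,
               bmd_log10_sd: float = 0.2,
               bmr_log2: float = None) -> TruthTable:
    """Draw a per-gene truth table for a given design.

    By default 10% of genes respond, split evenly across Hill, exponential
    and linear shapes; effect amplitudes at saturation are uniform in
    ``amplitude_range`` log2 units.  When ``bmd_log10_centers`` is given,
    responsive genes are assigned target true BMDs drawn from a balanced
    Gaussian mixture on the log10(µM) axis and the curve scale parameter is
    solved so the true BMD (at ``bmr_log2``) hits the target.  Otherwise
    targets are spread log-uniformly over the nonzero concentration range.

    ``bmr_log2`` defaults to one delta-method noise SD of log2 counts at the
    median baseline (the same "1 x control SD" convention the analysis uses).
    """
    rng = np.random.default_rng(seed)
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, n_genes))
    baseline = np.clip(baseline, 1.0, None)
    if bmr_log2 is None:
        bmr_log2 = float(log2_noise_sd(np.median(baseline), dispersion))

    n_resp = int(round(responsive_fraction * n_genes))
    resp_idx = rng.choice(n_genes, size=n_resp, replace=False)
    responsive = np.zeros(n_genes, dtype=bool)
    responsive[resp_idx] = True

    cmax = design.max_conc
    cmin = design.min_nonzero_conc
    if bmd_log10_centers is not None:
        centers = rng.choice(len(bmd_log10_centers), size=n_resp)
        target = 10.0 ** (np.array(bmd_log10_centers)[centers]
                          + rng.normal(0.0, bmd_log10_sd, n_resp))
    else:
        target = 10.0 ** rng.uniform(math.log10(cmin), math.log10(cmax), n_resp)
    target = np.clip(target, cmin / 5.0, cmax)

    shapes = np.array(["hill", "exp", "linear"])[np.arange(n_resp) % 3]
    rng.shuffle(shapes)
    amps = rng.uniform(*amplitude_range, n_resp)
    signs = rng.choice([-1.0, 1.0], n_resp)

    curves = [ResponseCurve("null")] * n_genes
    true_bmd = np.full(n_genes, np.nan)
    for j, gi in enumerate(sorted(resp_idx)):
        amp, b = signs[j] * amps[j], target[j]
        if shapes[j] == "linear":
            # slope chosen so |slope| * b = bmr; saturates at the amplitude
            cv = ResponseCurve("linear", {"slope": math.copysign(bmr_log2 / b,
                                                                 amp),
                                          "cap": abs(amp)})
        elif shapes[j] == "exp":
            # amplitude fixed; solve rate so amp*(1-exp(-r b)) = +/- bmr
            frac = bmr_log2 / abs(amp)
            if frac >= 1:
                frac = 0.8
            rate = -math.log(1.0 - frac) / b
            cv = ResponseCurve("exp", {"amplitude": amp, "rate": rate})
        else:
            # Hill with coefficient n; solve k so amp*b^n/(k^n+b^n) = +/- bmr
            n = float(rng.uniform(1.0, 3.0))
            frac = min(bmr_log2 / abs(amp), 0.8)
            k = b * ((1.0 - frac) / frac) ** (1.0 / n)
            cv = ResponseCurve("hill", {"k": k, "n": n, "amplitude": amp})
        curves[gi] = cv
        true_bmd[gi] = true_bmd_of(cv, bmr_log2, c_max=cmax)

    frame = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n_genes)],
        "baseline_mean": baseline,
        "dispersion": dispersion,
        "responsive": responsive,
        "curve_json": [c.to_json() for c in curves],
        "true_bmd": true_bmd,
    })
    return TruthTable(frame=frame, bmr_log2=bmr_log2)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw gene x sample integer counts with the sample sheet."""

    counts: pd.DataFrame           # genes in rows, samples in columns
    samples: pd.DataFrame          # sample_id, concentration_uM, replicate

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns must match sample sheet order")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self):
        return self.counts.index

    def concentrations(self) -> np.ndarray:
        return self.samples["concentration_uM"].to_numpy(float)


def simulate_counts(design: DoseDesign, truth: TruthTable,
                    library_size: float = 200_000.0, seed: int = 0,
                    library_size_log_sd: float = 0.1) -> CountMatrix:
    """Draw a negative-binomial count matrix under the truth table.

    Per sample, gene means are ``baseline * 2**curve(concentration)``
    rescaled so the expected column total equals that sample's library size
    (lognormal jitter, sigma = ``library_size_log_sd``).  Counts use a
    counter-based RNG stream per gene, so extending the truth table with more
    genes never reshuffles counts of existing genes.  ``dispersion = 0`` is
    the Poisson limit.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    frame = truth.frame
    if (frame["dispersion"] < 0).any():
        raise ValueError("dispersion must be non-negative")

    sheet = design.sample_sheet()
    concs = sheet["concentration_uM"].to_numpy(float)
    baseline = frame["baseline_mean"].to_numpy(float)
    phi = frame["dispersion"].to_numpy(float)
    n_genes, n_samp = len(frame), len(sheet)

    shift = np.empty((n_genes, n_samp))
    for gi, cv in enumerate(truth.curves()):
        shift[gi] = cv(concs)
    mu = baseline[:, None] * np.exp2(shift)

    depth_rng = np.random.default_rng([seed, 0xD5])
    lib = library_size * np.exp(depth_rng.normal(0.0, library_size_log_sd,
                                                 n_samp))
    mu *= lib / mu.sum(axis=0)

    counts = np.empty((n_genes, n_samp), dtype=np.int64)
    for gi in range(n_genes):
        g = np.random.default_rng([seed, 1, gi])
        m = mu[gi]
        if phi[gi] == 0.0:
            counts[gi] = g.poisson(m)
        else:
            r = 1.0 / phi[gi]
            counts[gi] = g.negative_binomial(r, r / (r + m))

    cdf = pd.DataFrame(counts, index=frame["gene_id"].to_numpy(),
                       columns=sheet["sample_id"].to_numpy())
    cdf.index.name = "gene_id"
    return CountMatrix(counts=cdf, samples=sheet)
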