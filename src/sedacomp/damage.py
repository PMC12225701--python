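"""Age-damage authentication model for sedimentary ancient DNA.

Post-mortem cytosine deamination converts C to U, read as T, concentrated at
fragment ends.  For each (genus, sample) observation the per-position C->T
counts k_x out of n_x opportunities are modelled as

    k_x ~ Binomial(n_x, A * (1 - q)**(x - 1) + c),   x = 1..max_pos

where A is the damage amplitude (excess C->T frequency at position 1), q the
per-position decay and c the background mismatch rate.  The fit is maximum
likelihood under bounds; the amplitude's standard error comes from the
observed information (inverse Hessian of the negative log-likelihood) and
z = A / se(A) is a Wald significance statistic.

Authentication calibrates a *minimum expected amplitude per age* from
terrestrial plant taxa — material that must have been transported through
the water column, so its damage is a conservative floor for in-situ
organisms of the same age.  Qualifying plant fits (>= 500 reads, z >= 2)
form calibration points; the envelope at age a is the running minimum of
calibration amplitudes up to a, linearly interpolated.  An observation is
authenticated *ancient* when its amplitude is significant and reaches the
envelope at its sample's age; ages younger than the earliest calibration
point are unassessable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .taxonomy import TaxonomyTree

__all__ = [
    "DamageFit",
    "AgeDamageEnvelope",
    "fit_damage",
    "build_envelope",
    "classify_ancient",
    "ANCIENT",
    "NOT_DAMAGED",
    "UNASSESSABLE",
]

ANCIENT = "ancient"
NOT_DAMAGED = "not_damaged"
UNASSESSABLE = "unassessable"


@dataclass
class DamageFit:
    """Fitted damage profile for one (taxon, sample) observation."""

    A: float          # amplitude: excess C->T frequency at position 1
    q: float          # per-position decay
    c: float          # background mismatch rate
    se_A: float       # Wald standard error of A
    z: float          # A / se_A
    n_reads: int      # reads behind the tallies (max n_x)
    converged: bool = True

    def curve(self, x: np.ndarray) -> np.ndarray:
        return self.A * (1.0 - self.q) ** (np.asarray(x) - 1) + self.c


def _nll(params: np.ndarray, x: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    a, q, c = params
    p = np.clip(a * (1.0 - q) ** (x - 1) + c, 1e-12, 1.0 - 1e-12)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def _hessian(f, params: np.ndarray, step: float = 1e-5) -> np.ndarray:
    m = len(params)
    h = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = step
            ej = np.zeros(m); ej[j] = step
            h[i, j] = h[j, i] = (
                f(params + ei + ej) - f(params + ei - ej)
                - f(params - ei + ej) + f(params - ei - ej)
            ) / (4 * step * step)
    return h


def fit_damage(k, n, max_starts: int = 4) -> DamageFit:
    """Maximum-likelihood fit of the exponential-decay damage curve.

    ``k``/``n`` are per-position mismatch counts and opportunities for
    positions 1..len(k); at least 4 positions with n > 0 are required.
    Bounds: A, c in [0, 1], q in [0, 0.99].  Flat or empty profiles resolve
    to A ~ 0 with small z rather than an error.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.shape != n.shape:
        raise ValueError("k and n must have the same length")
    if (k > n).any():
        raise ValueError("k must not exceed n")
    usable = n > 0
    if usable.sum() < 4:
        raise ValueError("need at least 4 positions with observations")
    x = np.arange(1, len(k) + 1, dtype=float)[usable]
    k, n = k[usable], n[usable]
    n_reads = int(n.max())

    freq = k / n
    bounds = [(0.0, 1.0), (0.0, 0.99), (0.0, 1.0)]
    c0 = float(np.clip(freq[len(freq) // 2:].mean(), 1e-4, 0.5))
    a0 = float(np.clip(freq[0] - c0, 1e-3, 0.9))
    starts = [
        (a0, 0.3, c0),
        (a0, 0.6, c0),
        (1e-3, 0.3, c0),
        (0.3, 0.35, 0.01),
    ][:max_starts]

    best = None
    for s in starts:
        res = minimize(_nll, np.asarray(s), args=(x, k, n),
                       method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    a_hat, q_hat, c_hat = best.x

    # observed information; A at the zero boundary can make it singular
    hess = _hessian(lambda p: _nll(np.clip(p, [0, 0, 0], [1, 0.99, 1]), x, k, n),
                    best.x)
    se_a = np.nan
    try:
        cov = np.linalg.inv(hess)
        var_a = cov[0, 0]
        if var_a > 0:
            se_a = float(np.sqrt(var_a))
    except np.linalg.LinAlgError:
        pass
    if not np.isfinite(se_a) or se_a <= 0:
        # fallback: binomial error on the position-1 excess frequency
        se_a = float(np.sqrt(max(freq[0], 1.0 / n[0]) * (1 - freq[0]) / n[0]) + 1e-12)
    z = a_hat / se_a
    return DamageFit(float(a_hat), float(q_hat), float(c_hat),
                     se_a, float(z), n_reads, bool(best.success))


def fit_damage_table(damage_table: pd.DataFrame) -> pd.DataFrame:
    """Fit every (genus, sample) group of a long damage-count table
    (columns genus, sample, position, k, n).  Returns one row per group with
    the fitted parameters."""
    rows = []
    for (genus, sample), grp in damage_table.groupby(["genus", "sample"]):
        grp = grp.sort_values("position")
        fit = fit_damage(grp["k"].to_numpy(), grp["n"].to_numpy())
        rows.append({
            "genus": genus, "sample": sample,
            "A": fit.A, "q": fit.q, "c": fit.c,
            "se_A": fit.se_A, "z": fit.z, "n_reads": fit.n_reads,
        })
    return pd.DataFrame(rows)


@dataclass
class AgeDamageEnvelope:
    """Minimum authenticated amplitude as a function of sediment age.

    ``ages``/``amplitudes`` are the calibration points (sorted by age,
    amplitudes already reduced to the running minimum in ``running_min``
    mode or per-bin minima in ``bin_min`` mode).  Between calibration ages
    the envelope interpolates linearly; beyond the oldest point it is
    constant; younger than the earliest point it is undefined
    (authentication impossible there).
    """

    ages: np.ndarray
    amplitudes: np.ndarray
    mode: str = "running_min"

    def __post_init__(self):
        if len(self.ages) < 2:
            raise ValueError("envelope needs at least 2 calibration points")

    def __call__(self, age: float) -> float | None:
        if age < self.ages[0]:
            return None
        return float(np.interp(age, self.ages, self.amplitudes))

    def to_json(self) -> str:
        return json.dumps({"mode": self.mode,
                           "ages": self.ages.tolist(),
                           "amplitudes": self.amplitudes.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "AgeDamageEnvelope":
        d = json.loads(text)
        return cls(np.asarray(d["ages"], dtype=float),
                   np.asarray(d["amplitudes"], dtype=float), d["mode"])


def build_envelope(fits: pd.DataFrame, tree: TaxonomyTree, plant_root: int,
                   sample_ages: dict[str, float] | pd.Series,
                   exclusions: tuple[int, ...] = (),
                   min_reads: int = 500, min_z: float = 2.0,
                   mode: str = "running_min",
                   bin_width: float = 1000.0) -> AgeDamageEnvelope | None:
    """Calibrate the age-damage envelope from terrestrial plant fits.

    ``fits`` has one row per (genus, sample) with columns genus, sample, A,
    z, n_reads.  Calibration points are plant-clade genera (descending from
    ``plant_root`` and from no excluded clade, e.g. eelgrass) with
    ``n_reads >= min_reads`` and ``z >= min_z``.  ``mode`` selects the
    running-minimum envelope (default) or per-age-bin minima.  Returns None
    (with a warning) when fewer than 2 calibration points qualify.
    """
    ages = pd.Series(sample_ages)
    plant = fits["genus"].map(
        lambda g: tree.is_reference_plant(int(g), plant_root, exclusions))
    ok = fits[plant & (fits["n_reads"] >= min_reads) & (fits["z"] >= min_z)]
    if len(ok) < 2:
        warnings.warn("fewer than 2 qualifying plant calibration points; "
                      "envelope unavailable, observations cannot be authenticated")
        return None
    pts = pd.DataFrame({"age": ok["sample"].map(ages).to_numpy(),
                        "A": ok["A"].to_numpy()})
    if mode == "running_min":
        pts = pts.groupby("age", as_index=False)["A"].min().sort_values("age")
        amp = np.minimum.accumulate(pts["A"].to_numpy())
        return AgeDamageEnvelope(pts["age"].to_numpy(dtype=float), amp, mode)
    if mode == "bin_min":
        pts["bin"] = (pts["age"] // bin_width) * bin_width + bin_width / 2
        binned = pts.groupby("bin", as_index=False)["A"].min().sort_values("bin")
        if len(binned) < 2:
            warnings.warn("fewer than 2 populated age bins; envelope unavailable")
            return None
        return AgeDamageEnvelope(binned["bin"].to_numpy(dtype=float),
                                 binned["A"].to_numpy(), mode)
    raise ValueError(f"unknown envelope mode {mode!r}")


def classify_ancient(A: float, z: float, age: float,
                     envelope: AgeDamageEnvelope | None,
                     min_z: float = 2.0) -> str:
    """Authenticate one observation against the envelope.

    *ancient* iff z >= min_z and A >= envelope(age) (inclusive comparisons:
    boundary observations are not silently discarded); *not_damaged* when
    assessable but failing either condition; *unassessable* when the
    envelope is undefined at this age (no calibration point that young, or
    no envelope at all).
    """
    if envelope is None:
        return UNASSESSABLE
    floor = envelope(age)
    if floor is None:
        return UNASSESSABLE
    return ANCIENT if (z >= min_z and A >= floor) else NOT_DAMAGED


def classify_table(fits: pd.DataFrame, envelope: AgeDamageEnvelope | None,
                   sample_ages: dict[str, float] | pd.Series,
                   min_z: float = 2.0) -> pd.DataFrame:
    """Vectorised ``classify_ancient`` over a fit table; adds ``age`` and
    ``status`` columns."""
    ages = pd.Series(sample_ages)
    out = fits.copy()
    out["age"] = out["sample"].map(ages)
    out["status"] = [
        classify_ancient(row.A, row.z, row.age, envelope, min_z)
        for row in out.itertuples()
    ]
    return out
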