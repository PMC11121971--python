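"""Seeded generators emulating each pipeline stage's inputs.

Each generator is pure given (config, seed): repeated calls return
byte-identical arrays.  Generator truth values (planted coefficients,
plateau degradation degrees, closed-form Mn/Mw of a truncated chain
length distribution) are computed directly from the configured
distributions, independently of the estimators they are used to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from oligodeg.biodegradation import BODSeries
from oligodeg.oligomer_ms import PeakList

__all__ = [
    "PlantedPLSConfig",
    "BODCurveConfig",
    "FloryConfig",
    "gen_pls_dataset",
    "gen_bod_series",
    "gen_flory_peaklist",
    "gen_random_smiles",
]


# ---------------------------------------------------------------------------
# planted latent-factor regression data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPLSConfig:
    """Descriptor-like design matrix with a planted linear response.

    The informative columns are built mutually orthogonal and orthogonal
    to the correlated nuisance block, so that with ``noise_sd = 0`` a
    PLS model recovers the response exactly with ``n_informative``
    latent variables.  ``noise_sd`` is relative to the signal standard
    deviation.
    """

    n_samples: int = 100
    n_descriptors: int = 18
    n_informative: int = 5
    beta: tuple[float, ...] | None = None
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_informative <= self.n_descriptors:
            raise ValueError("need 1 <= n_informative <= n_descriptors")
        if self.n_descriptors >= self.n_samples:
            raise ValueError("the planted design needs n_samples > n_descriptors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_pls_dataset(cfg: PlantedPLSConfig) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Return (X, y, beta_true) with y = X beta_true + noise."""
    rng = np.random.default_rng(cfg.seed)
    n, p, k = cfg.n_samples, cfg.n_descriptors, cfg.n_informative

    # column-centred before QR so every factor is orthogonal to the
    # intercept: model centring then leaves the planted geometry intact
    g = rng.standard_normal((n, p))
    g -= g.mean(axis=0)
    q, _ = np.linalg.qr(g)
    # descriptor-like column scales spanning two orders of magnitude
    scales = 10.0 ** rng.uniform(-1, 1, p)
    informative = q[:, :k]
    nuisance_dirs = q[:, k:]
    mixing = rng.standard_normal((p - k, p - k)) if p > k else np.empty((0, 0))
    nuisance = nuisance_dirs @ mixing if p > k else np.empty((n, 0))

    X = np.hstack([informative, nuisance]) * scales
    order = rng.permutation(p)
    X = X[:, order]

    beta = np.zeros(p)
    planted = np.asarray(cfg.beta, float) if cfg.beta is not None else rng.uniform(1.0, 3.0, k)
    if len(planted) != k:
        raise ValueError("beta must have n_informative entries")
    informative_positions = np.where(order < k)[0]
    beta[informative_positions] = planted[order[informative_positions]] / scales[order][
        informative_positions
    ]

    signal = X @ beta
    noise = rng.standard_normal(n) * cfg.noise_sd * signal.std(ddof=1)
    y = signal + noise
    cols = [f"D{i + 1}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y, beta


# ---------------------------------------------------------------------------
# first-order BOD uptake curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BODCurveConfig:
    """First-order oxygen-uptake curve with lag, blank offset and noise.

    ``dt_inf`` is the plateau degradation degree (percent of ThOD
    ultimately consumed), ``k`` the first-order rate (1/day) and
    ``lag`` the lag phase (days).
    """

    dt_inf: float = 40.0
    k: float = 0.15
    lag: float = 2.0
    blank_level: float = 3.0  # mg/L
    noise_sd: float = 0.0  # mg/L
    thod: float = 1.5  # mg O2 / mg substance
    conc: float = 100.0  # mg/L
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dt_inf <= 100:
            raise ValueError("dt_inf must be a percentage in [0, 100]")
        if self.k < 0 or self.lag < 0:
            raise ValueError("rate and lag must be non-negative")


def gen_bod_series(
    cfg: BODCurveConfig, times, sample_id: str = "synthetic"
) -> tuple[BODSeries, np.ndarray]:
    """Return a noisy blank-inclusive BOD series and the true Dt curve."""
    times = np.asarray(times, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(cfg.seed)
    uptake = 1.0 - np.exp(-cfg.k * np.maximum(times - cfg.lag, 0.0))
    true_dt = cfg.dt_inf * uptake
    bod_true = true_dt / 100.0 * cfg.thod * cfg.conc
    noise = rng.standard_normal(len(times)) * cfg.noise_sd
    bod_measured = np.maximum(bod_true + cfg.blank_level + noise, 0.0)
    blank = np.full(len(times), cfg.blank_level)
    series = BODSeries(
        sample_id=sample_id,
        times=tuple(times),
        bod=tuple(bod_measured),
        blank_bod=tuple(blank),
        conc=cfg.conc,
    )
    return series, true_dt


# ---------------------------------------------------------------------------
# Flory most-probable oligomer peak lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FloryConfig:
    """Most-probable (Flory) chain-length distribution for ESI-MS peaks.

    Chain length n carries neutral mass ``end_mass + n * repeat_mass``;
    abundances follow the weight fraction n p^(n-1) (1-p)^2 by default,
    or the number fraction (1-p) p^(n-1) when ``fraction='number'``.
    """

    p: float = 0.5
    repeat_mass: float = 210.18
    end_mass: float = 18.02
    adduct_mass: float = 22.99
    n_max: int = 30
    abundance_noise: float = 0.0  # relative, multiplicative
    fraction: str = "weight"  # weight | number
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p < 1:
            raise ValueError("extent of reaction p must be in [0, 1)")
        if self.n_max < 2:
            raise ValueError("n_max must be at least 2")
        if self.fraction not in ("weight", "number"):
            raise ValueError("fraction must be 'weight' or 'number'")


def flory_truth(cfg: FloryConfig) -> tuple[float, float]:
    """Closed-form Mn and Mw of the truncated distribution.

    Computed by direct summation over n = 1..n_max, treating the
    configured abundance fractions as the peak intensities N_i that a
    spectrum summariser would see.
    """
    n = np.arange(1, cfg.n_max + 1)
    mass = cfg.end_mass + n * cfg.repeat_mass
    if cfg.fraction == "weight":
        frac = n * cfg.p ** (n - 1) * (1 - cfg.p) ** 2
    else:
        frac = (1 - cfg.p) * cfg.p ** (n - 1)
    mn = float((frac * mass).sum() / frac.sum())
    mw = float((frac * mass**2).sum() / (frac * mass).sum())
    return mn, mw


def gen_flory_peaklist(cfg: FloryConfig) -> tuple[PeakList, float, float]:
    """Return (peak list, true Mn, true Mw); m/z = neutral mass + adduct."""
    rng = np.random.default_rng(cfg.seed)
    n = np.arange(1, cfg.n_max + 1)
    mass = cfg.end_mass + n * cfg.repeat_mass
    if cfg.fraction == "weight":
        frac = n * cfg.p ** (n - 1) * (1 - cfg.p) ** 2
    else:
        frac = (1 - cfg.p) * cfg.p ** (n - 1)
    abundance = frac * 1.0e4
    if cfg.abundance_noise > 0:
        abundance = abundance * np.exp(
            rng.standard_normal(len(n)) * cfg.abundance_noise
        )
    mn, mw = flory_truth(cfg)
    peaks = PeakList.from_arrays(mass + cfg.adduct_mass, abundance)
    return peaks, mn, mw


# ---------------------------------------------------------------------------
# random small molecules for descriptor property testing
# ---------------------------------------------------------------------------

_ATOM_CHOICES = ("C", "C", "C", "C", "O", "N")


def gen_random_smiles(
    n_molecules: int,
    seed: int = 0,
    *,
    min_heavy: int = 3,
    max_heavy: int = 9,
) -> list[str]:
    """Random small CHON molecules as SMILES (seeded, valid by construction).

    Chains of C/O/N atoms with occasional methyl branches and carbonyl
    decorations -- enough chemical variety (alcohols, ethers, amines,
    ketones, acids) to exercise every descriptor code path.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n_molecules:
        n_heavy = int(rng.integers(min_heavy, max_heavy + 1))
        atoms = [str(rng.choice(_ATOM_CHOICES)) for _ in range(n_heavy)]
        # avoid adjacent heteroatoms to keep valences simple
        for i in range(1, n_heavy):
            if atoms[i] != "C" and atoms[i - 1] != "C":
                atoms[i] = "C"
        parts = []
        for i, a in enumerate(atoms):
            parts.append(a)
            if a == "C" and 0 < i < n_heavy - 1:
                r = rng.random()
                if r < 0.15:
                    parts.append("(C)")
                elif r < 0.25:
                    parts.append("(=O)")
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        out.append(Chem.MolToSmiles(mol))
    return out
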