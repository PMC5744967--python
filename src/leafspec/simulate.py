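"""Synthetic study generator: a dry-down experiment on a small poplar stand.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without field data:

* `n_trees` trees sampled on `n_dates` weekly dates;
* photosynthetic capacity (Vcmax, Jmax) declining roughly two-fold over the
  period along a logistic trajectory, with an extra stress-driven dip;
* predawn water potential (psi_pd) dipping mid-period, with between-tree
  spread in stress susceptibility that makes the population psi variance
  peak on the stress date and the date after it;
* a forward-modelled 13-step A/Ci curve per leaf with additive noise;
* replicate reflectance spectra on the 350-2500 nm 1-nm grid built from a
  smooth analytic green-leaf template: chlorophyll absorption wells
  (blue ~465 nm, red ~668 nm) and a red-edge shift that deepen/advance
  monotonically with Vcmax, and water absorption wells (~1450, ~1940 nm)
  that deepen as psi_pd becomes less negative (wetter leaf).  The water
  wells couple the SWIR to water status and act as the stress-dependent
  spectral confound; set ``water_psi_gain=0`` to disable.

The template is an analytic caricature, not a radiative-transfer model:
adequate for testing the statistics, not for optical realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fvcb import CI_PROTOCOL_PPM, ACiCurve, KineticConstants, fvcb_assimilation
from .spectra import Spectrum

__all__ = [
    "SyntheticConfig",
    "StudyRecord",
    "StudyTable",
    "simulate_traits",
    "simulate_aci",
    "simulate_spectrum",
    "simulate_study",
    "write_study",
    "read_aci_csv",
    "read_spectra_csv",
]

_GRID = np.arange(350.0, 2501.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design constants and noise levels for the synthetic experiment.

    Defaults encode the study conditions: 12 trees, 7 weekly dates, a
    ~2-fold capacity decline (110 -> 55 umol m-2 s-1), Jmax/Vcmax ~ 1.98,
    9 replicate spectra per leaf, stress peaking late mid-period.
    """

    n_trees: int = 12
    n_dates: int = 7
    date_spacing_days: int = 7
    vcmax_start_mean: float = 110.0      # umol m-2 s-1
    vcmax_end_mean: float = 55.0         # umol m-2 s-1
    jmax_ratio: float = 1.98             # Jmax/Vcmax
    tree_sd: float = 6.0                 # between-tree offset, umol m-2 s-1
    psi_base: float = -0.3               # well-watered predawn psi, MPa
    psi_stress_depth: float = 0.9        # max extra psi depression, MPa
    stress_peak_date_index: int = 4
    psi_sd: float = 0.05                 # iid psi noise, MPa
    psi_tree_cv: float = 0.35            # between-tree stress susceptibility CV
    stress_width_dates: float = 0.8      # Gaussian width of stress pulse
    stress_gain: float = 12.0            # Vcmax dip per MPa of psi depression
    jmax_cv: float = 0.05                # multiplicative Jmax noise CV
    jmax_stress_sensitivity: float = 0.15  # extra Jmax reduction per MPa stress
    aci_rd: float = 1.0                  # day respiration used in forward curves
    aci_noise_sd: float = 0.5            # additive A noise, umol m-2 s-1
    spectral_noise_sd: float = 0.005     # additive reflectance noise
    n_replicate_spectra: int = 9
    water_depth_base: float = 0.10       # water-well depth at psi = -1.5 MPa
    water_psi_gain: float = 0.10         # extra depth per MPa above -1.5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_trees >= 1, "n_trees must be >= 1"),
            (self.n_dates >= 1, "n_dates must be >= 1"),
            (self.n_replicate_spectra >= 1, "n_replicate_spectra must be >= 1"),
            (self.vcmax_end_mean < self.vcmax_start_mean,
             "vcmax_end_mean must be below vcmax_start_mean (dry-down decline)"),
            (self.vcmax_end_mean > 0, "vcmax_end_mean must be positive"),
            (self.jmax_ratio > 0, "jmax_ratio must be positive"),
            (self.tree_sd >= 0, "tree_sd must be >= 0"),
            (self.psi_sd >= 0, "psi_sd must be >= 0"),
            (self.aci_noise_sd >= 0, "aci_noise_sd must be >= 0"),
            (self.spectral_noise_sd >= 0, "spectral_noise_sd must be >= 0"),
            (0 <= self.stress_peak_date_index < self.n_dates,
             "stress_peak_date_index must lie in [0, n_dates)"),
            (self.psi_base <= 0, "psi_base must be <= 0 (water potential)"),
            (self.psi_stress_depth >= 0, "psi_stress_depth must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class StudyRecord:
    tree_id: int
    date_index: int
    psi_pd: float
    true_vcmax: float
    true_jmax: float
    aci_curve: ACiCurve | None = None
    spectra: list[Spectrum] = field(default_factory=list)


@dataclass
class StudyTable:
    """One record per (tree, date): traits, psi, A/Ci curve, spectra."""

    records: list[StudyRecord]
    config: SyntheticConfig

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"tree": r.tree_id, "date": r.date_index, "psi_pd": r.psi_pd,
             "true_vcmax": r.true_vcmax, "true_jmax": r.true_jmax}
            for r in self.records])


def _stress_profile(cfg: SyntheticConfig) -> np.ndarray:
    """Gaussian-in-time stress pulse, exactly zero at the first and last
    dates and renormalised to peak 1.

    The centre sits 0.4 dates after `stress_peak_date_index`, so the peak
    date carries the strictly largest stress and the following date the
    second largest — fixing which consecutive date pair a stress holdout
    selects.
    """
    t = np.arange(cfg.n_dates, dtype=float)
    if cfg.n_dates == 1:
        return np.zeros(1)
    center = cfg.stress_peak_date_index + 0.4
    g = np.exp(-((t - center) ** 2) / (2.0 * cfg.stress_width_dates ** 2))
    g = np.clip(g - max(g[0], g[-1]), 0.0, None)
    peak = g.max()
    return g / peak if peak > 0 else g


def _trajectory(cfg: SyntheticConfig) -> np.ndarray:
    """Logistic-in-time mean Vcmax decline, hitting both endpoints exactly."""
    t = np.arange(cfg.n_dates, dtype=float)
    if cfg.n_dates == 1:
        return np.array([cfg.vcmax_start_mean])
    mid = (cfg.n_dates - 1) / 2.0
    g = 1.0 / (1.0 + np.exp(1.0 * (t - mid)))
    g = (g - g[-1]) / (g[0] - g[-1])
    return cfg.vcmax_end_mean + (cfg.vcmax_start_mean - cfg.vcmax_end_mean) * g


def simulate_traits(config: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> StudyTable:
    """Draw psi_pd and true (Vcmax, Jmax) for every (tree, date).

    Per-tree Vcmax follows the logistic decline plus a constant tree offset
    minus a dip proportional to the psi depression below `psi_base`; Jmax is
    `jmax_ratio` x Vcmax with multiplicative noise (CV `jmax_cv`) and a small
    additional stress sensitivity that decouples it from Vcmax under water
    stress.  Reproducible given the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    cfg = config
    traj = _trajectory(cfg)
    pulse = _stress_profile(cfg)
    tree_offsets = rng.normal(0.0, cfg.tree_sd, size=cfg.n_trees) if cfg.tree_sd > 0 \
        else np.zeros(cfg.n_trees)
    # lognormal susceptibility: mean 1, positive
    if cfg.psi_tree_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.psi_tree_cv ** 2))
        suscept = rng.lognormal(-0.5 * sigma ** 2, sigma, size=cfg.n_trees)
    else:
        suscept = np.ones(cfg.n_trees)
    records = []
    for i in range(cfg.n_trees):
        for t in range(cfg.n_dates):
            noise = rng.normal(0.0, cfg.psi_sd) if cfg.psi_sd > 0 else 0.0
            psi = cfg.psi_base - cfg.psi_stress_depth * pulse[t] * suscept[i] + noise
            psi = min(psi, 0.0)
            depression = max(cfg.psi_base - psi, 0.0)
            vcmax = traj[t] + tree_offsets[i] - cfg.stress_gain * depression
            vcmax = max(vcmax, 5.0)
            jnoise = rng.normal(0.0, cfg.jmax_cv) if cfg.jmax_cv > 0 else 0.0
            jmax = (cfg.jmax_ratio * vcmax * (1.0 + jnoise)
                    * (1.0 - cfg.jmax_stress_sensitivity * depression))
            jmax = max(jmax, 5.0)
            records.append(StudyRecord(tree_id=i, date_index=t, psi_pd=psi,
                                       true_vcmax=vcmax, true_jmax=jmax))
    return StudyTable(records=records, config=cfg)


def simulate_aci(true_vcmax: float, true_jmax: float, config: SyntheticConfig,
                 rng: np.random.Generator | None = None,
                 k: KineticConstants | None = None) -> ACiCurve:
    """Forward-model the 13-step chamber protocol with additive A noise."""
    if true_vcmax <= 0 or true_jmax <= 0:
        raise ValueError("traits must be positive")
    rng = rng or np.random.default_rng(config.seed)
    ci = np.array(CI_PROTOCOL_PPM)
    a = fvcb_assimilation(ci, true_vcmax, true_jmax, config.aci_rd, k=k)
    if config.aci_noise_sd > 0:
        a = a + rng.normal(0.0, config.aci_noise_sd, size=ci.size)
    return ACiCurve(ci=ci, a=a)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_spectrum(true_vcmax: float, psi_pd: float, config: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> Spectrum:
    """One replicate reflectance spectrum on the 350-2500 nm 1-nm grid.

    Higher Vcmax deepens the chlorophyll wells and shifts the red edge to
    longer wavelengths (strictly lower reflectance at 680 nm, higher
    rho750/rho700); less negative psi_pd (wetter leaf) deepens the 1450 and
    1940 nm water wells.  Additive Gaussian noise, clipped to [0, 1].
    """
    if true_vcmax <= 0:
        raise ValueError("true_vcmax must be positive")
    if psi_pd > 0:
        raise ValueError("psi_pd must be <= 0")
    rng = rng or np.random.default_rng(config.seed)
    wl = _GRID
    chl = (true_vcmax - 30.0) / 100.0  # normalised chlorophyll proxy, ~0.2-0.9

    def well(center, width):
        return np.exp(-((wl - center) ** 2) / (2.0 * width ** 2))

    vis = (0.17
           - (0.085 + 0.050 * chl) * well(465.0, 35.0)
           - (0.070 + 0.060 * chl) * well(668.0, 27.0))
    water_depth = (config.water_depth_base
                   + config.water_psi_gain * max(psi_pd + 1.5, 0.0))
    nir = (0.47
           - 0.00008 * np.clip(wl - 1300.0, 0.0, None)     # gentle SWIR slope
           - water_depth * (0.75 * well(1450.0, 45.0) + well(1940.0, 60.0)))
    edge = _sigmoid((wl - (690.0 + 30.0 * chl)) / 18.0)
    refl = vis * (1.0 - edge) + nir * edge
    if config.spectral_noise_sd > 0:
        refl = refl + rng.normal(0.0, config.spectral_noise_sd, size=wl.size)
    return Spectrum(wl, np.clip(refl, 0.0, 1.0))


def simulate_study(config: SyntheticConfig | None = None) -> StudyTable:
    """Generate the full synthetic study: traits, A/Ci curves, spectra."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    table = simulate_traits(cfg, rng=rng)
    for rec in table.records:
        rec.aci_curve = simulate_aci(rec.true_vcmax, rec.true_jmax, cfg, rng=rng)
        rec.aci_curve.label = f"tree{rec.tree_id:02d}_date{rec.date_index}"
        rec.spectra = [simulate_spectrum(rec.true_vcmax, rec.psi_pd, cfg, rng=rng)
                       for _ in range(cfg.n_replicate_spectra)]
    return table


# ---------------------------------------------------------------------------
# plain-text I/O


def write_study(table: StudyTable, outdir: str | Path) -> None:
    """Write a study as tidy CSVs: study.csv, aci/<leaf>.csv, spectra/<leaf>.csv."""
    outdir = Path(outdir)
    (outdir / "aci").mkdir(parents=True, exist_ok=True)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(outdir / "study.csv", index=False)
    for rec in table.records:
        stem = f"tree{rec.tree_id:02d}_date{rec.date_index}"
        if rec.aci_curve is not None:
            pd.DataFrame({"Ci_ppm": rec.aci_curve.ci,
                          "A_umol_m2_s": rec.aci_curve.a}
                         ).to_csv(outdir / "aci" / f"{stem}.csv", index=False)
        if rec.spectra:
            cols = {"wavelength_nm": rec.spectra[0].wavelengths}
            for j, s in enumerate(rec.spectra):
                cols[f"rep{j + 1}"] = s.reflectance
            pd.DataFrame(cols).to_csv(outdir / "spectra" / f"{stem}.csv",
                                      index=False)


def read_aci_csv(path: str | Path) -> ACiCurve:
    df = pd.read_csv(path)
    return ACiCurve(ci=df["Ci_ppm"].to_numpy(),
                    a=df["A_umol_m2_s"].to_numpy(), label=Path(path).stem)


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    wl = df["wavelength_nm"].to_numpy()
    return [Spectrum(wl, df[c].to_numpy(), label=f"{Path(path).stem}:{c}")
            for c in df.columns if c != "wavelength_nm"]
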