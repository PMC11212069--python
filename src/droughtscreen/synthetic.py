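"""Seeded simulator of a randomized-complete-block split-plot drought trial.

The generator emulates the screening design: two water regimes (WS
well-watered, WD water-deficit) applied to whole plots within each block,
a set of ecotypes on sub-plots, and several morpho-physiological traits
measured per pot.  Each trait is generated on a link scale where Gaussian
effects are additive and then mapped back, so domain constraints hold by
construction: log for positive/count traits, logit for proportions (and
percentages via /100), identity for unconstrained traits.

On the link scale:

    eta_ijk = link(mu_WS) + block_i + wholeplot_ij + ecotype_k
              + 1[j = WD] * (m_k * Delta + g_k) + e_ijk

where ``Delta = link(mu_WS * (1 + drought_effect)) - link(mu_WS)`` is the
regime shift reproducing the trait's average relative change under
stress, and ``m_k`` is the multiplier of the ecotype's latent tolerance
class (tolerant ecotypes have the smallest expected relative loss).  With
all variances zero and multipliers 1, every WD value equals
``mu_WS * (1 + drought_effect)`` exactly.

Randomness is split into one substream per (trait, stratum) derived from
the master seed, so adding or removing a trait never perturbs the draws
of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trait_data import OBS_COLUMNS

CLASSES = ("tolerant", "moderate", "sensitive")


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class TraitGenSpec:
    """Generation parameters for one trait.

    ``mu_ws`` is the cohort-level WS mean on the natural scale;
    ``drought_effect`` the signed fractional change of the mean under WD
    (e.g. -0.438 = a 43.8 % reduction); sigmas are standard deviations on
    the link scale.
    """

    name: str
    mu_ws: float
    drought_effect: float
    sigma_block: float = 0.05
    sigma_wholeplot: float = 0.05
    sigma_ecotype: float = 0.12
    sigma_ge: float = 0.05
    sigma_resid: float = 0.30
    link: str = "log"              # log | logit | logit100 | identity
    integer: bool = False

    def _check(self) -> None:
        for s in ("sigma_block", "sigma_wholeplot", "sigma_ecotype",
                  "sigma_ge", "sigma_resid"):
            if getattr(self, s) < 0:
                raise ValueError(f"{self.name}: {s} must be >= 0")
        if not -1.0 <= self.drought_effect <= 1.0:
            raise ValueError(f"{self.name}: drought_effect outside [-1, 1]")
        mu_wd = self.mu_ws * (1.0 + self.drought_effect)
        if self.link == "log" and (self.mu_ws <= 0 or mu_wd <= 0):
            raise ValueError(f"{self.name}: log link needs positive means")
        if self.link == "logit" and not (0 < self.mu_ws < 1 and 0 < mu_wd < 1):
            raise ValueError(f"{self.name}: logit link needs means in (0, 1)")
        if self.link == "logit100" and not (0 < self.mu_ws < 100 and 0 < mu_wd < 100):
            raise ValueError(f"{self.name}: logit100 link needs means in (0, 100)")

    def to_link(self, x):
        if self.link == "log":
            return np.log(x)
        if self.link == "logit":
            return _logit(x)
        if self.link == "logit100":
            return _logit(np.asarray(x) / 100.0)
        if self.link == "identity":
            return np.asarray(x, dtype=float)
        raise ValueError(f"unknown link {self.link!r}")

    def from_link(self, eta):
        if self.link == "log":
            return np.exp(eta)
        if self.link == "logit":
            return _expit(eta)
        if self.link == "logit100":
            return 100.0 * _expit(eta)
        return np.asarray(eta, dtype=float)


#: Default traits, calibrated to the screening trial's grand-mean rows
#: (WS means and average relative changes under WD) with dispersions
#: bracketing the printed CV% rows.  PhiNPQ increases under stress.
def default_traits() -> list[TraitGenSpec]:
    return [
        TraitGenSpec("PH", 14.9, -0.438, sigma_resid=0.35),
        TraitGenSpec("NT", 5.07, -0.241, sigma_resid=0.50, integer=True),
        TraitGenSpec("NL", 4.82, -0.297, sigma_resid=0.25, integer=True),
        TraitGenSpec("RL", 75.53, -0.315, sigma_resid=0.25),
        TraitGenSpec("FWT", 12.0, -0.84, sigma_resid=0.30),
        TraitGenSpec("DMY", 4.0, -0.668, sigma_resid=0.30, sigma_ecotype=0.05),
        TraitGenSpec("RWC", 74.27, -0.859, sigma_resid=0.50, link="logit100"),
        TraitGenSpec("Phi2", 0.36, -0.50, sigma_resid=0.40, link="logit"),
        TraitGenSpec("PhiNPQ", 0.60, +0.283, sigma_resid=0.20, link="logit"),
        TraitGenSpec("SPAD", 37.14, -0.853, sigma_resid=0.40),
        TraitGenSpec("FvFm", 0.41, -0.439, sigma_resid=0.30, link="logit"),
    ]


def default_classes(n_ecotypes: int) -> tuple[str, ...]:
    """Latent tolerance classes: ~2/7 tolerant, 3/7 moderate, 2/7 sensitive
    (10/15/10 at the default cohort size of 35)."""
    n_tol = round(n_ecotypes * 10 / 35)
    n_sen = round(n_ecotypes * 10 / 35)
    n_mod = n_ecotypes - n_tol - n_sen
    return ("tolerant",) * n_tol + ("moderate",) * n_mod + ("sensitive",) * n_sen


@dataclass(frozen=True)
class GeneratorConfig:
    n_ecotypes: int = 35
    n_blocks: int = 5
    traits: tuple[TraitGenSpec, ...] = field(
        default_factory=lambda: tuple(default_traits()))
    tolerance_classes: tuple[str, ...] | None = None  # None -> default split
    class_multipliers: dict[str, float] = field(
        default_factory=lambda: {"tolerant": 0.5, "moderate": 1.0,
                                 "sensitive": 1.5})
    seed: int = 0

    def classes(self) -> tuple[str, ...]:
        cls = (self.tolerance_classes
               if self.tolerance_classes is not None
               else default_classes(self.n_ecotypes))
        if len(cls) != self.n_ecotypes:
            raise ValueError("tolerance_classes length != n_ecotypes")
        unknown = set(cls) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown tolerance class(es): {unknown}")
        return tuple(cls)

    def validate(self) -> None:
        if self.n_ecotypes < 1 or self.n_blocks < 1:
            raise ValueError("n_ecotypes and n_blocks must be >= 1")
        if not self.traits:
            raise ValueError("at least one trait required")
        for t in self.traits:
            t._check()
        m = self.class_multipliers
        if not (m["tolerant"] <= m["moderate"] <= m["sensitive"]):
            raise ValueError(
                "class multipliers must be ordered tolerant <= moderate "
                "<= sensitive (tolerant = smallest expected loss)")
        self.classes()

    def ecotype_names(self) -> list[str]:
        width = len(str(self.n_ecotypes))
        return [f"E{i + 1:0{width}d}" for i in range(self.n_ecotypes)]


def null_config(n_ecotypes: int = 35, n_blocks: int = 5, *,
                sigma_resid: float = 1.0, seed: int = 0) -> GeneratorConfig:
    """Config with no ecotype or interaction effects (for test-size
    calibration): identity link, Gaussian errors, all class multipliers
    equal and ecotype/interaction variances zero."""
    trait = TraitGenSpec("Y", mu_ws=10.0, drought_effect=-0.3,
                         sigma_block=0.5, sigma_wholeplot=0.5,
                         sigma_ecotype=0.0, sigma_ge=0.0,
                         sigma_resid=sigma_resid, link="identity")
    return GeneratorConfig(
        n_ecotypes=n_ecotypes, n_blocks=n_blocks, traits=(trait,),
        class_multipliers={"tolerant": 1.0, "moderate": 1.0, "sensitive": 1.0},
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Latent state of a simulated trial, regenerable from (config, seed)."""

    classes: pd.Series                   # ecotype -> class
    expected_ys: pd.Series | None        # noise-free DMY mean under WD
    expected_yp: pd.Series | None        # noise-free DMY mean under WS
    ecotype_effects: pd.DataFrame        # trait x ecotype (link scale)
    ge_draws: pd.DataFrame               # trait x ecotype (link scale)


def _rng(seed: int, trait: str, stratum: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(seed) % 2**31,
             zlib.crc32(trait.encode()),
             zlib.crc32(stratum.encode())]))


def simulate_trial(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one balanced split-plot trial.

    Returns the long observation table (ecotype, water_regime, block,
    trait, value) and the ground truth.  Identical (config, seed) yields
    identical output.
    """
    config.validate()
    ecos = config.ecotype_names()
    classes = config.classes()
    mult = np.array([config.class_multipliers[c] for c in classes])
    r, b = config.n_blocks, config.n_ecotypes
    regimes = ["WS", "WD"]

    frames = []
    eco_eff_rows, ge_rows = {}, {}
    exp_ys = exp_yp = None
    for t in config.traits:
        blk = _rng(config.seed, t.name, "block").normal(0, t.sigma_block, r)
        wp = _rng(config.seed, t.name, "wholeplot").normal(
            0, t.sigma_wholeplot, (r, 2))
        eco = _rng(config.seed, t.name, "ecotype").normal(0, t.sigma_ecotype, b)
        ge = _rng(config.seed, t.name, "ge").normal(0, t.sigma_ge, b)
        eps = _rng(config.seed, t.name, "resid").normal(
            0, t.sigma_resid, (r, 2, b))

        mu_link = t.to_link(t.mu_ws)
        delta = t.to_link(t.mu_ws * (1.0 + t.drought_effect)) - mu_link
        wd_shift = mult * delta + ge     # per-ecotype shift under WD

        eta = (mu_link
               + blk[:, None, None]
               + wp[:, :, None]
               + eco[None, None, :]
               + np.array([0.0, 1.0])[None, :, None] * wd_shift[None, None, :]
               + eps)
        vals = t.from_link(eta)
        if t.integer:
            vals = np.maximum(np.rint(vals), 0.0)
        idx = pd.MultiIndex.from_product(
            [range(1, r + 1), regimes, ecos],
            names=["block", "water_regime", "ecotype"])
        frames.append(pd.DataFrame({
            "trait": t.name, "value": vals.reshape(-1)}, index=idx
        ).reset_index())
        eco_eff_rows[t.name] = eco
        ge_rows[t.name] = ge
        if t.name == "DMY":
            exp_yp = pd.Series(t.from_link(mu_link + eco), index=ecos)
            exp_ys = pd.Series(t.from_link(mu_link + eco + wd_shift), index=ecos)

    obs = pd.concat(frames, ignore_index=True)[OBS_COLUMNS]
    truth = GroundTruth(
        classes=pd.Series(classes, index=ecos, name="class"),
        expected_ys=exp_ys, expected_yp=exp_yp,
        ecotype_effects=pd.DataFrame(eco_eff_rows, index=ecos).T,
        ge_draws=pd.DataFrame(ge_rows, index=ecos).T,
    )
    return obs, truth


def expected_means(trait: TraitGenSpec, multiplier: float = 1.0) -> tuple[float, float]:
    """Noise-free (median) WS and WD means of a trait for one class
    multiplier — the deterministic backbone of the generator."""
    mu_link = trait.to_link(trait.mu_ws)
    delta = trait.to_link(trait.mu_ws * (1.0 + trait.drought_effect)) - mu_link
    return (float(trait.from_link(mu_link)),
            float(trait.from_link(mu_link + multiplier * delta)))


def simulate_leaf_rwc_samples(
    config: GeneratorConfig,
    targets: dict[str, float] | None = None,
    *,
    tw: float = 10.0,
    dw: float = 2.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Per-ecotype (FWT, TW, DW) weight triples hitting a class-specific
    target relative water content.

    ``targets`` maps tolerance class to target RWC in (0, 100); defaults
    reflect stressed leaves (tolerant 20 %, moderate 10 %, sensitive 4 %).
    The implied RWC equals the target up to the optional Gaussian noise on
    FWT (truncated to [DW, TW] so TW >= FWT >= DW always holds).
    """
    config.validate()
    if targets is None:
        targets = {"tolerant": 20.0, "moderate": 10.0, "sensitive": 4.0}
    for c, t in targets.items():
        if not (0.0 <= t <= 100.0):
            raise ValueError(f"target RWC for {c} outside [0, 100]: {t}")
    if not (tw > dw > 0):
        raise ValueError("need TW > DW > 0")
    ecos = config.ecotype_names()
    classes = config.classes()
    rng = _rng(config.seed, "RWC_samples", "fwt")
    rows = []
    for eco, cls in zip(ecos, classes):
        fwt = dw + targets[cls] / 100.0 * (tw - dw)
        if noise_sd > 0:
            fwt = float(np.clip(fwt + rng.normal(0, noise_sd), dw, tw))
        rows.append({"ecotype": eco, "class": cls,
                     "FWT": fwt, "TW": tw, "DW": dw})
    return pd.DataFrame(rows)
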