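"""Configuration of the synthetic paired-cohort generator.

The generator emulates a single-group crossover study: every subject is
measured at each of several visits, and each visit corresponds to a treatment
condition. Features live in named blocks (e-nose sensor arrays, NMR metabolite
integrals, eicosanoid concentrations, FeNO, spirometry, sputum differential
counts). Concentration-like blocks are simulated on the log scale and
exponentiated, so visit effects are multiplicative and values stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError

FAMILIES = ("positive-lognormal", "gaussian")

#: visit labels of the study design this package emulates:
#: V1 screening (fluticasone/salmeterol maintenance), V2 baseline
#: (beclomethasone/formoterol run-in), V3 post-withdrawal (formoterol alone),
#: V4 post-treatment (beclomethasone/formoterol).
DEFAULT_VISITS = ("V1", "V2", "V3", "V4")


def _as_feature_array(value, n_features: int, field_name: str, block: str) -> np.ndarray:
    """Broadcast a scalar or per-feature sequence to a float array of length p."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_features, float(arr[0]))
    if arr.shape != (n_features,):
        raise ConfigError(
            f"block {block!r}: {field_name} must be a scalar or have one entry "
            f"per feature ({n_features}), got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class BlockSpec:
    """One feature block of the simulated cohort.

    Parameters
    ----------
    name:
        Block identifier, e.g. ``"carbon_polymer"``.
    features:
        Feature (column) names, unique within the block.
    family:
        ``"positive-lognormal"`` simulates on the log scale and exponentiates
        (concentration-like, strictly positive); ``"gaussian"`` is additive on
        the natural scale (e.g. spirometric indices).
    baseline:
        Latent-scale location per feature (log of the typical value for the
        lognormal family). Scalar or per-feature.
    sigma_s:
        Between-subject SD of the random subject baseline. Scalar or
        per-feature.
    sigma_e:
        Residual (within-subject, visit-to-visit) SD. Scalar or per-feature.
    rho:
        Within-block correlation, induced by one shared latent factor with
        loading sqrt(rho) in both the subject effect and the residual, so the
        latent correlation between any two features of the block equals rho.
    """

    name: str
    features: tuple[str, ...]
    family: str = "gaussian"
    baseline: float | Sequence[float] = 0.0
    sigma_s: float | Sequence[float] = 1.0
    sigma_e: float | Sequence[float] = 0.5
    rho: float = 0.0

    @property
    def n_features(self) -> int:
        return len(self.features)

    def baseline_array(self) -> np.ndarray:
        return _as_feature_array(self.baseline, self.n_features, "baseline", self.name)

    def sigma_s_array(self) -> np.ndarray:
        return _as_feature_array(self.sigma_s, self.n_features, "sigma_s", self.name)

    def sigma_e_array(self) -> np.ndarray:
        return _as_feature_array(self.sigma_e, self.n_features, "sigma_e", self.name)

    def validate(self) -> None:
        if not self.features:
            raise ConfigError(f"block {self.name!r}: features must be non-empty")
        if len(set(self.features)) != len(self.features):
            raise ConfigError(f"block {self.name!r}: features contains duplicates")
        if self.family not in FAMILIES:
            raise ConfigError(
                f"block {self.name!r}: family must be one of {FAMILIES}, got {self.family!r}"
            )
        if np.any(self.sigma_s_array() < 0):
            raise ConfigError(f"block {self.name!r}: sigma_s must be >= 0")
        if np.any(self.sigma_e_array() <= 0):
            raise ConfigError(f"block {self.name!r}: sigma_e must be > 0")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError(f"block {self.name!r}: rho must satisfy 0 <= rho < 1")
        self.baseline_array()  # shape check


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of a simulated paired multi-block cohort.

    ``effects`` maps ``(block, feature, visit)`` to an additive shift on the
    latent scale (log scale for lognormal blocks), relative to the unshifted
    baseline condition. ``missingness`` maps block name to a per-cell missing
    probability (missing completely at random).
    """

    n_subjects: int = 14
    visits: tuple[str, ...] = DEFAULT_VISITS
    blocks: tuple[BlockSpec, ...] = ()
    effects: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    missingness: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def block(self, name: str) -> BlockSpec:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if len(set(self.visits)) != len(self.visits):
            raise ConfigError(f"visits must be distinct, got {self.visits}")
        if len(self.visits) < 2:
            raise ConfigError("visits must contain at least 2 labels")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ConfigError("block names must be unique")
        for b in self.blocks:
            b.validate()
        for (block, feat, visit), delta in self.effects.items():
            spec = self._lookup_block(block, "effects")
            if feat not in spec.features:
                raise ConfigError(f"effects: unknown feature {feat!r} in block {block!r}")
            if visit not in self.visits:
                raise ConfigError(f"effects: unknown visit {visit!r}")
            float(delta)
        for block, prob in self.missingness.items():
            self._lookup_block(block, "missingness")
            if not (0.0 <= prob <= 1.0):
                raise ConfigError(
                    f"missingness[{block!r}] must be in [0, 1], got {prob}"
                )

    def _lookup_block(self, name: str, field_name: str) -> BlockSpec:
        try:
            return self.block(name)
        except KeyError:
            raise ConfigError(f"{field_name}: unknown block {name!r}") from None


# ---------------------------------------------------------------------------
# Default study-like configuration
# ---------------------------------------------------------------------------

# Typical carbon-polymer sensor responses (relative resistance change,
# (Rmax-R0)/R0): a 32-sensor array with widely varying per-sensor magnitudes
# and strong cross-sensor redundancy.
_CARBON_LEVELS = (
    2.507, 1.664, 2.527, 1.447, 11.27, 6.574, 0.001109, 0.6803,
    2.154, 1.283, 1.277, 1.321, 1.036, 0.8994, 2.225, 1.241,
    1.430, 2.643, 0.9070, 2.341, 0.8288, 1.004, 9.586, 1.403,
    1.426, 0.003672, 0.0005989, 0.004238, 2.228, 0.9987, 15.13, 0.6599,
)

# Typical quartz-microbalance responses (relative frequency change, Hz).
_QUARTZ_LEVELS = (21.5, 19.0, 49.0, 31.0, 12.5, 24.0, 20.5, 30.5)

# EBC NMR metabolite integrals (arbitrary units), typical levels.
_NMR_LEVELS = {
    "acetate": 7322.0,
    "acetoine": 706.0,
    "acetone": 6152.0,
    "hydroxyisovalerate_3": 326.0,
    "ethanol": 488.0,
    "formate": 695.0,
    "lactate": 444.0,
    "leucine_n_butyrate": 1432.0,
    "methanol": 14225.0,
    "n_butyrate": 664.0,
    "phenol": 443.0,
    "propionate": 1543.0,
    "trimethylamine": 365.0,
}

_SPIRO_FEATURES = (
    # (name, baseline, sigma_s, sigma_e)
    ("fev1_l", 1.66, 0.79, 0.07),
    ("fev1_pct_pred", 61.8, 25.8, 2.5),
    ("fvc_l", 2.80, 1.05, 0.10),
    ("fvc_pct_pred", 79.9, 23.6, 3.0),
    ("fev1_fvc_pct", 58.1, 12.0, 1.2),
    ("pef_l_s", 4.81, 2.43, 0.25),
    ("pef_pct_pred", 65.5, 30.3, 3.2),
    ("fef2575_l_s", 0.92, 0.52, 0.05),
    ("fef2575_pct_pred", 32.4, 17.2, 1.6),
)

_SPUTUM_FEATURES = (
    ("neutrophils_pct", 65.0, 12.0, 6.0),
    ("macrophages_pct", 25.0, 10.0, 5.0),
    ("eosinophils_pct", 1.0, 0.8, 0.5),
    ("lymphocytes_pct", 2.0, 1.2, 0.8),
    ("epithelial_pct", 5.0, 3.0, 2.0),
)


def _default_effects() -> dict[tuple[str, str, str], float]:
    """ICS-responsive default effect template (latent/log scale, vs V1).

    Qualitative pattern: e-nose responses drift upward after the inhaler
    switch and most at the final combination-treatment visit; sputum PGE2
    rises under formoterol alone (steroid withdrawal) and falls back under
    either steroid combination; EBC formate and acetate fall under the final
    combination treatment. Magnitudes are free simulator parameters.
    """
    effects: dict[tuple[str, str, str], float] = {}
    for i in range(32):
        f = f"cp{i + 1:02d}"
        effects[("carbon_polymer", f, "V2")] = 0.12
        effects[("carbon_polymer", f, "V3")] = 0.15
        effects[("carbon_polymer", f, "V4")] = 0.25
    for i in range(8):
        f = f"qc{i + 1}"
        effects[("quartz", f, "V2")] = 0.30
        effects[("quartz", f, "V3")] = 0.25
        effects[("quartz", f, "V4")] = 0.35
    effects[("nmr", "formate", "V3")] = -0.45
    effects[("nmr", "formate", "V4")] = -0.50
    effects[("nmr", "acetate", "V3")] = 0.35
    effects[("nmr", "acetate", "V4")] = -0.45
    effects[("eicosanoids", "sputum_pge2", "V2")] = 0.25
    effects[("eicosanoids", "sputum_pge2", "V3")] = 0.55
    spiro = {
        ("fev1_l", "V2"): 0.02, ("fev1_l", "V3"): -0.01, ("fev1_l", "V4"): 0.01,
        ("fev1_pct_pred", "V2"): 0.9, ("fev1_pct_pred", "V3"): 0.1,
        ("fev1_pct_pred", "V4"): 0.6,
        ("fvc_l", "V2"): 0.06, ("fvc_l", "V3"): 0.12, ("fvc_l", "V4"): 0.11,
        ("fvc_pct_pred", "V2"): 1.9, ("fvc_pct_pred", "V3"): 4.1,
        ("fvc_pct_pred", "V4"): 3.4,
        ("fev1_fvc_pct", "V2"): -0.9, ("fev1_fvc_pct", "V3"): -2.8,
        ("fev1_fvc_pct", "V4"): -1.8,
        ("pef_l_s", "V2"): 0.43, ("pef_l_s", "V3"): 0.08, ("pef_l_s", "V4"): 0.12,
        ("pef_pct_pred", "V2"): 5.8, ("pef_pct_pred", "V3"): 1.3,
        ("pef_pct_pred", "V4"): 1.7,
        ("fef2575_l_s", "V2"): 0.02, ("fef2575_l_s", "V3"): -0.06,
        ("fef2575_l_s", "V4"): 0.0,
        ("fef2575_pct_pred", "V2"): 0.5, ("fef2575_pct_pred", "V3"): -2.2,
        ("fef2575_pct_pred", "V4"): 0.2,
    }
    for (feat, visit), delta in spiro.items():
        effects[("spirometry", feat, visit)] = delta
    return effects


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-like default: 14 subjects, 4 visits, 7 blocks, 63 features."""
    blocks = (
        BlockSpec(
            name="carbon_polymer",
            features=tuple(f"cp{i + 1:02d}" for i in range(32)),
            family="positive-lognormal",
            baseline=tuple(log(v) for v in _CARBON_LEVELS),
            sigma_s=0.35,
            sigma_e=0.15,
            rho=0.90,
        ),
        BlockSpec(
            name="quartz",
            features=tuple(f"qc{i + 1}" for i in range(8)),
            family="positive-lognormal",
            baseline=tuple(log(v) for v in _QUARTZ_LEVELS),
            sigma_s=0.35,
            sigma_e=0.20,
            rho=0.85,
        ),
        BlockSpec(
            name="nmr",
            features=tuple(_NMR_LEVELS),
            family="positive-lognormal",
            baseline=tuple(log(v) for v in _NMR_LEVELS.values()),
            sigma_s=0.45,
            sigma_e=0.55,
            rho=0.20,
        ),
        BlockSpec(
            name="eicosanoids",
            features=("sputum_pge2", "ebc_pge2", "sputum_isoprostane", "ebc_isoprostane"),
            family="positive-lognormal",
            baseline=(log(150.0), log(15.0), log(40.0), log(10.0)),
            sigma_s=0.40,
            sigma_e=0.35,
            rho=0.30,
        ),
        BlockSpec(
            name="feno",
            features=("feno_ppb",),
            family="positive-lognormal",
            baseline=log(18.0),
            sigma_s=0.40,
            sigma_e=0.25,
            rho=0.0,
        ),
        BlockSpec(
            name="spirometry",
            features=tuple(f[0] for f in _SPIRO_FEATURES),
            family="gaussian",
            baseline=tuple(f[1] for f in _SPIRO_FEATURES),
            sigma_s=tuple(f[2] for f in _SPIRO_FEATURES),
            sigma_e=tuple(f[3] for f in _SPIRO_FEATURES),
            rho=0.60,
        ),
        BlockSpec(
            name="sputum",
            features=tuple(f[0] for f in _SPUTUM_FEATURES),
            family="gaussian",
            baseline=tuple(f[1] for f in _SPUTUM_FEATURES),
            sigma_s=tuple(f[2] for f in _SPUTUM_FEATURES),
            sigma_e=tuple(f[3] for f in _SPUTUM_FEATURES),
            rho=0.30,
        ),
    )
    cfg = SyntheticConfig(
        n_subjects=14,
        visits=DEFAULT_VISITS,
        blocks=blocks,
        effects=_default_effects(),
        missingness={"eicosanoids": 0.03, "sputum": 0.03},
        seed=seed,
    )
    cfg.validate()
    return cfg


def null_config(seed: int = 0, **kwargs) -> SyntheticConfig:
    """Default config with all treatment effects removed (pure null)."""
    return replace(default_config(seed=seed), effects={}, **kwargs)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return {
        "n_subjects": cfg.n_subjects,
        "visits": list(cfg.visits),
        "blocks": [
            {
                "name": b.name,
                "features": list(b.features),
                "family": b.family,
                "baseline": _scalar_or_list(b.baseline),
                "sigma_s": _scalar_or_list(b.sigma_s),
                "sigma_e": _scalar_or_list(b.sigma_e),
                "rho": b.rho,
            }
            for b in cfg.blocks
        ],
        "effects": [
            {"block": k[0], "feature": k[1], "visit": k[2], "delta": float(v)}
            for k, v in cfg.effects.items()
        ],
        "missingness": dict(cfg.missingness),
        "seed": cfg.seed,
    }


def _scalar_or_list(value):
    if np.isscalar(value):
        return float(value)
    return [float(v) for v in np.atleast_1d(np.asarray(value, dtype=float))]


def config_from_dict(d: Mapping) -> SyntheticConfig:
    blocks = tuple(
        BlockSpec(
            name=b["name"],
            features=tuple(b["features"]),
            family=b.get("family", "gaussian"),
            baseline=_tuple_or_scalar(b.get("baseline", 0.0)),
            sigma_s=_tuple_or_scalar(b.get("sigma_s", 1.0)),
            sigma_e=_tuple_or_scalar(b.get("sigma_e", 0.5)),
            rho=float(b.get("rho", 0.0)),
        )
        for b in d.get("blocks", [])
    )
    effects = {
        (e["block"], e["feature"], e["visit"]): float(e["delta"])
        for e in d.get("effects", [])
    }
    cfg = SyntheticConfig(
        n_subjects=int(d.get("n_subjects", 14)),
        visits=tuple(d.get("visits", DEFAULT_VISITS)),
        blocks=blocks,
        effects=effects,
        missingness={k: float(v) for k, v in dict(d.get("missingness", {})).items()},
        seed=int(d.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def _tuple_or_scalar(value):
    if isinstance(value, (list, tuple)):
        return tuple(float(v) for v in value)
    return float(value)


def save_config(cfg: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
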