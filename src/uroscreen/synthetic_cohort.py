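"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

No per-sample data accompany the study being emulated, so testing the
pipeline end-to-end needs a generator whose cohorts *look like* urine
screening data: a minority of culture-positive samples (~17.4%
prevalence), right-skewed non-negative particle counts in both channels,
higher counts in culture-positive samples, and device-specific count
scales (two analysers reporting the same biology on scales ~25-fold
apart).

Counts are class-conditional bivariate log-normals.  On the log scale the
two classes are Gaussian, so the single-channel AUC has the closed
binormal form

    AUC = Φ( (μ_pos − μ_neg) / sqrt(σ_neg² + σ_pos²) ),

which makes calibration exact: :func:`calibrate_separation` inverts the
formula, and the default device profiles pin each channel's population
AUC to the published figure-level values (device "A", flow-cytometer-like:
bacteria 0.943, WBC 0.832; device "B", flow-microscopy-like: 0.864 and
0.834) — calibration inputs for the simulator, not claims about real
data.  Device "B" additionally carries ``scale_shift = −log(138/5.7)``,
an additive log-scale offset on both channels that multiplies every count
(hence every optimal cut-off) by exp(shift) while leaving AUC and all
(se, sp) operating points unchanged.

All distribution parameters are this package's own calibrated choices;
the anchor means and sigmas (negative bacteria median ≈ 44/μL on device
A, log-sd 1.4; negative WBC median 10/μL) are picked so simulated
operating points land in the neighbourhood of published cut-offs, and the
serialized :class:`GeneratorConfig` records them in full.

Reproducibility: one seed spawns one child random stream per sample index
(``numpy`` SeedSequence), so enlarging ``n`` extends a cohort without
reshuffling earlier samples.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .metrics import ContractError
from .samples_io import Cohort, CultureLabelConfig, UrineSample

__all__ = [
    "ChannelModel",
    "DeviceProfile",
    "GeneratorConfig",
    "binormal_auc",
    "calibrate_separation",
    "default_device_profile",
    "generate_cohort",
]

# AUC calibration targets for the two default device profiles
DEVICE_AUC_TARGETS = {
    "A": {"bacteria": 0.943, "wbc": 0.832},
    "B": {"bacteria": 0.864, "wbc": 0.834},
}
# device B reports ~25-fold lower counts (cut-off contrast 138 vs 5.7 /μL)
DEVICE_B_SCALE_SHIFT = -float(np.log(138.0 / 5.7))

_LOG_SD = 1.4                      # log-scale sd, both classes and channels
_BAC_POS_MU = float(np.log(100.0) + norm.ppf(0.95) * _LOG_SD)  # se=0.95 cutoff near 100/μL
_WBC_NEG_MU = float(np.log(10.0))  # negative WBC median 10/μL
_RHO = 0.3                         # mild within-class bacteria–WBC coupling


def binormal_auc(mu_neg: float, mu_pos: float, sigma_neg: float, sigma_pos: float) -> float:
    """Closed-form AUC of two Gaussian classes: Φ(Δμ / sqrt(σn²+σp²))."""
    if not (sigma_neg > 0 and sigma_pos > 0):
        raise ContractError("sigmas must be > 0")
    return float(norm.cdf((mu_pos - mu_neg) / np.hypot(sigma_neg, sigma_pos)))


def calibrate_separation(target_auc: float, sigma_neg: float, sigma_pos: float) -> float:
    """Mean separation μ_pos − μ_neg achieving a target binormal AUC."""
    if not (0.0 < target_auc < 1.0):
        raise ContractError(f"target_auc must lie in (0, 1), got {target_auc!r}")
    if not (sigma_neg > 0 and sigma_pos > 0):
        raise ContractError("sigmas must be > 0")
    return float(norm.ppf(target_auc) * np.hypot(sigma_neg, sigma_pos))


@dataclass(frozen=True)
class ChannelModel:
    """Class-conditional log-normal model of one count channel.

    ``mu_*``/``sigma_*`` are log-scale (natural log of counts/μL) means
    and standard deviations for the culture-negative and culture-positive
    classes.  ``rho`` is the within-class correlation between log-bacteria
    and log-WBC; the generator uses the bacteria channel's value for the
    joint draw.
    """

    mu_neg: float
    mu_pos: float
    sigma_neg: float
    sigma_pos: float
    rho: float = _RHO

    def __post_init__(self) -> None:
        if not (self.sigma_neg > 0 and self.sigma_pos > 0):
            raise ContractError("sigmas must be > 0")
        if not (-1.0 < self.rho < 1.0):
            raise ContractError(f"|rho| must be < 1, got {self.rho!r}")

    @property
    def auc(self) -> float:
        """Population AUC of this channel."""
        return binormal_auc(self.mu_neg, self.mu_pos, self.sigma_neg, self.sigma_pos)


@dataclass(frozen=True)
class DeviceProfile:
    """Two channel models plus an additive log-scale device offset.

    ``scale_shift`` rescales both channels' counts by exp(shift): optimal
    cut-offs move with it, AUC and (se, sp) operating points do not.
    """

    name: str
    bac_model: ChannelModel
    wbc_model: ChannelModel
    scale_shift: float = 0.0


def default_device_profile(name: str = "A") -> DeviceProfile:
    """Built-in calibrated profile "A" (cytometer-like) or "B" (microscopy-like)."""
    key = name.strip().upper()
    if key not in DEVICE_AUC_TARGETS:
        raise ContractError(f"unknown device profile {name!r}; choose from A, B")
    targets = DEVICE_AUC_TARGETS[key]
    sep_bac = calibrate_separation(targets["bacteria"], _LOG_SD, _LOG_SD)
    sep_wbc = calibrate_separation(targets["wbc"], _LOG_SD, _LOG_SD)
    bac = ChannelModel(
        mu_neg=_BAC_POS_MU - sep_bac, mu_pos=_BAC_POS_MU,
        sigma_neg=_LOG_SD, sigma_pos=_LOG_SD,
    )
    wbc = ChannelModel(
        mu_neg=_WBC_NEG_MU, mu_pos=_WBC_NEG_MU + sep_wbc,
        sigma_neg=_LOG_SD, sigma_pos=_LOG_SD,
    )
    shift = DEVICE_B_SCALE_SHIFT if key == "B" else 0.0
    return DeviceProfile(name=key, bac_model=bac, wbc_model=wbc, scale_shift=shift)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full stochastic description of a synthetic cohort.

    Defaults emulate the study conditions: n = 1220 samples at prevalence
    213/1220 ≈ 0.1746, with 5% of truth-negative samples flagged as
    contaminated cultures (their counts drawn from an intermediate model
    midway between the class means).
    """

    n: int = 1220
    prevalence: float = 213 / 1220
    contamination_rate: float = 0.05
    device: DeviceProfile = field(default_factory=default_device_profile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ContractError(f"n must be >= 1, got {self.n}")
        for name in ("prevalence", "contamination_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ContractError(f"{name} must lie in [0, 1], got {value!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        out = plain(asdict(self))
        out["note"] = (
            "synthetic cohort; all distribution parameters are calibrated "
            "choices of the uroscreen package, not fitted to instrument data"
        )
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        data.pop("note", None)
        device = data.get("device")
        if isinstance(device, dict):
            device = dict(device)
            for key in ("bac_model", "wbc_model"):
                if isinstance(device.get(key), dict):
                    device[key] = ChannelModel(**device[key])
            data["device"] = DeviceProfile(**device)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _contaminated_model(model: ChannelModel) -> tuple[float, float]:
    """Intermediate (mu, sigma): contaminated cultures sit between the classes."""
    return (0.5 * (model.mu_neg + model.mu_pos), model.sigma_neg)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a reproducible synthetic cohort.

    Per sample: truth class ~ Bernoulli(prevalence); log-counts from the
    class's bivariate normal (channel means/sigmas, correlation rho,
    plus the device scale_shift), exponentiated; truth-positive samples
    receive a culture load >= 1e5 CFU/mL and truth-negatives < 1e5;
    a ``contamination_rate`` fraction of truth-negatives is flagged
    contaminated with counts from the intermediate model.
    """
    device = config.device
    bac, wbc = device.bac_model, device.wbc_model
    rho = bac.rho
    chol = np.array([[1.0, 0.0], [rho, np.sqrt(1.0 - rho * rho)]])

    children = np.random.SeedSequence(config.seed).spawn(config.n)
    samples: list[UrineSample] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        positive = rng.random() < config.prevalence
        contaminated = (not positive) and (rng.random() < config.contamination_rate)
        if positive:
            mu_b, sd_b = bac.mu_pos, bac.sigma_pos
            mu_w, sd_w = wbc.mu_pos, wbc.sigma_pos
        elif contaminated:
            mu_b, sd_b = _contaminated_model(bac)
            mu_w, sd_w = _contaminated_model(wbc)
        else:
            mu_b, sd_b = bac.mu_neg, bac.sigma_neg
            mu_w, sd_w = wbc.mu_neg, wbc.sigma_neg
        z = chol @ rng.standard_normal(2)
        log_b = mu_b + sd_b * z[0] + device.scale_shift
        log_w = mu_w + sd_w * z[1] + device.scale_shift
        if positive:
            cfu = 10.0 ** (5.0 + 3.0 * rng.random())        # 1e5 .. 1e8
        elif contaminated:
            cfu = 10.0 ** (3.0 + 2.0 * rng.random())        # mixed growth, < 1e5
        else:
            cfu = 10.0 ** (5.0 * rng.random())              # < 1e5
        samples.append(UrineSample(
            sample_id=f"S{i:06d}",
            device=device.name,
            bacteria_per_uL=float(np.exp(log_b)),
            wbc_per_uL=float(np.exp(log_w)),
            culture_cfu_per_mL=float(cfu),
            contaminated=contaminated,
        ))
    return Cohort(samples=samples, label_config=CultureLabelConfig())
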