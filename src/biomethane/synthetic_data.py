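"""Seeded synthetic inputs for every pipeline stage.

No raw measurements are shipped with this package: the generator emulates the
statistical structure the analysis assumes — AMPTS-style hourly gas logs for
substrate channels (triplicate, at inoculum-to-substrate ratios 2/3/4) and
inoculum-only blanks, substrate-concentration decay series, and FT-ICR-MS
formula-assignment tables with prescribed Van Krevelen class shares.  Every
generator is a pure function of its configuration and seed, and stores its
ground truth alongside the data so analysis results can be checked against
what was simulated.

Default study conditions: first-order true methane kinetics per group with
ultimate yields ~344-375 mL/g VS and rate constants 0.55-0.64 1/d, a small
first-order endogenous blank, mesophilic meter conditions (308.15 K), 60%
CH4 in the biogas, 25-day hourly sampling, and additive Gaussian meter noise
of 0.3 mL per tick (about 2% of early-phase hourly increments).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dom_classify import DEFAULT_CLASS_BOXES, classify_vk
from .gas_preprocess import ChannelMeta, YieldCurve, normalize_to_stp
from .kinetics import KineticModelSpec, model_curve

DEFAULT_SEED = 20260302


@dataclass
class GroupConfig:
    label: str
    isr: float
    substrate_vs: float
    inoculum_vs: float
    replicates: int
    true_model: KineticModelSpec

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def default_groups() -> list[GroupConfig]:
    """Three substrate groups at ISR 2/3/4 with first-order true kinetics."""
    truths = {
        "HC2": {"B0": 343.76, "k": 0.62},
        "HC3": {"B0": 374.72, "k": 0.64},
        "HC4": {"B0": 364.76, "k": 0.55},
    }
    groups = []
    for isr, (label, p) in zip((2.0, 3.0, 4.0), truths.items()):
        groups.append(
            GroupConfig(
                label=label, isr=isr, substrate_vs=2.0, inoculum_vs=2.0 * isr,
                replicates=3, true_model=KineticModelSpec("first_order", dict(p)),
            )
        )
    return groups


@dataclass
class BMPSimConfig:
    groups: list[GroupConfig] = field(default_factory=default_groups)
    blank_model: KineticModelSpec = field(
        default_factory=lambda: KineticModelSpec("first_order", {"B0": 15.0, "k": 0.10})
    )  # per g inoculum VS
    blank_inoculum_vs: float = 6.0
    blank_replicates: int = 3
    noise_sd: float = 0.3  # mL, additive on incremental meter volumes, truncated at 0
    duration_d: float = 25.0
    sampling_interval_h: float = 1.0
    meter_temperature_k: float = 308.15
    meter_pressure_kpa: float = 101.325
    ch4_fraction: float = 0.6
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration_d <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("duration and sampling interval must be > 0")


@dataclass
class SimulatedBMP:
    gas_logs: pd.DataFrame  # standard gas-log columns, all channels stacked
    channel_meta: list[ChannelMeta]
    truth: dict  # per-group true spec/curves + blank curve per g inoculum VS
    config: BMPSimConfig


def _stp_factor(temperature_k: float, pressure_kpa: float) -> float:
    return (273.15 / temperature_k) * (pressure_kpa / 101.325)


def generate_bmp_dataset(config: BMPSimConfig | None = None) -> SimulatedBMP:
    """Simulate a full BMP run: substrate channels plus inoculum-only blanks.

    Per channel, incremental methane at STP is the first difference of
    (true specific curve x substrate VS + blank curve x inoculum VS); total
    biogas is methane / CH4 fraction, back-converted to meter conditions,
    with additive Gaussian noise truncated at zero.  Blanks carry only the
    endogenous background.
    """
    config = config or BMPSimConfig()
    rng = np.random.default_rng(config.seed)
    hours = np.arange(
        config.sampling_interval_h,
        config.duration_d * 24.0 + 1e-9,
        config.sampling_interval_h,
    )
    t_days = hours / 24.0
    stp = _stp_factor(config.meter_temperature_k, config.meter_pressure_kpa)

    blank_specific = model_curve(config.blank_model, t_days)  # mL CH4 / g inoculum VS

    frames, metas = [], []
    truth: dict = {
        "blank_curve_per_g_inoculum": YieldCurve(
            np.concatenate([[0.0], t_days]),
            np.concatenate([[0.0], blank_specific]),
        ),
        "groups": {},
        "seed": config.seed,
    }

    def make_channel(channel_id: str, methane_cum_stp: np.ndarray) -> pd.DataFrame:
        methane_inc = np.diff(methane_cum_stp, prepend=0.0)
        total_inc_meter = methane_inc / config.ch4_fraction / stp
        if config.noise_sd > 0:
            total_inc_meter = np.clip(
                total_inc_meter + rng.normal(0.0, config.noise_sd, total_inc_meter.shape),
                0.0, None,
            )
        return pd.DataFrame(
            {
                "channel_id": channel_id,
                "time_h": hours,
                "volume_increment_ml": total_inc_meter,
                "temperature_k": config.meter_temperature_k,
                "pressure_kpa": config.meter_pressure_kpa,
                "ch4_fraction": config.ch4_fraction,
            }
        )

    for g in config.groups:
        spec_cum = model_curve(g.true_model, t_days)  # mL CH4 / g substrate VS
        truth["groups"][g.label] = {
            "true_model": g.true_model,
            "true_curve": YieldCurve(
                np.concatenate([[0.0], t_days]), np.concatenate([[0.0], spec_cum])
            ),
        }
        for r in range(g.replicates):
            cid = f"{g.label}_r{r + 1}"
            methane = spec_cum * g.substrate_vs + blank_specific * g.inoculum_vs
            frames.append(make_channel(cid, methane))
            metas.append(
                ChannelMeta(channel_id=cid, group_label=g.label,
                            substrate_vs=g.substrate_vs, inoculum_vs=g.inoculum_vs,
                            is_blank=False, replicate_index=r + 1)
            )
    for r in range(config.blank_replicates):
        cid = f"blank_r{r + 1}"
        frames.append(make_channel(cid, blank_specific * config.blank_inoculum_vs))
        metas.append(
            ChannelMeta(channel_id=cid, group_label="blank", substrate_vs=0.0,
                        inoculum_vs=config.blank_inoculum_vs, is_blank=True,
                        replicate_index=r + 1)
        )
    return SimulatedBMP(
        gas_logs=pd.concat(frames, ignore_index=True),
        channel_meta=metas, truth=truth, config=config,
    )


def generate_yield_curve(
    spec: KineticModelSpec,
    times_days: np.ndarray,
    noise_frac: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> YieldCurve:
    """Specific cumulative methane curve from a model, with relative noise.

    Noise is additive Gaussian on the per-interval increments with standard
    deviation ``noise_frac`` times the increment, truncated at zero so the
    cumulative curve stays non-decreasing.  ``noise_frac=0`` returns the
    exact model curve.
    """
    t = np.asarray(times_days, dtype=float)
    clean = model_curve(spec, t)
    if noise_frac == 0:
        return YieldCurve(t, clean)
    rng = np.random.default_rng(seed)
    inc = np.diff(clean, prepend=clean[0] if t[0] > 0 else 0.0)
    noisy = np.clip(inc * (1.0 + rng.normal(0.0, noise_frac, inc.shape)), 0.0, None)
    return YieldCurve(t, np.cumsum(noisy))


def generate_substrate_series(
    s0: float,
    k_deg: float,
    times_days: np.ndarray,
    noise_cv: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> np.ndarray:
    """First-order substrate decay S0*exp(-k_deg t) with log-normal noise."""
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    if k_deg < 0:
        raise ValueError("k_deg must be >= 0")
    t = np.asarray(times_days, dtype=float)
    clean = s0 * np.exp(-k_deg * t)
    if noise_cv == 0:
        return clean
    rng = np.random.default_rng(seed)
    return np.clip(clean * rng.lognormal(0.0, noise_cv, t.shape), 0.0, None)


def default_class_shares() -> dict[str, float]:
    """Target Van Krevelen class shares: the three dominant classes of a
    carbohydrate-digestion liquor (62.57 / 22.97 / 11.00 %), remainder spread
    equally over the minor classes."""
    shares = {"lignin_cram": 62.57, "aliphatic_proteins": 22.97, "lipids": 11.00}
    minor = ("carbohydrates", "unsaturated_hc", "aromatic", "tannin")
    rest = (100.0 - sum(shares.values())) / len(minor)
    shares.update(dict.fromkeys(minor, rest))
    return shares


@dataclass
class DOMSimConfig:
    n_formulas: int = 5000
    class_shares: dict[str, float] = field(default_factory=default_class_shares)
    element_group_probs: dict[str, float] = field(
        default_factory=lambda: {"CHO": 0.55, "CHON": 0.35, "CHOS": 0.05, "CHONS": 0.05}
    )
    intensity_sigma: float = 1.0  # log-normal sigma of relative intensities
    c_range: tuple[int, int] = (4, 40)
    sample_id: str = "SYN_0h"
    max_retries: int = 500
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_formulas < 1:
            raise ValueError("n_formulas must be >= 1")
        if sum(self.class_shares.values()) > 100.0 + 1e-9:
            raise ValueError("class shares must sum to <= 100")


def _sample_formula_in_box(rng: np.random.Generator, box, c_range, max_retries) -> tuple[int, int, int]:
    """Rejection-sample integer (c, h, o) whose H/C, O/C ratios classify into
    the intended box under the default precedence rule."""
    name, hc_lo, hc_hi, oc_lo, oc_hi = box
    for _ in range(max_retries):
        c = int(rng.integers(c_range[0], c_range[1] + 1))
        hc = rng.uniform(hc_lo, hc_hi)
        oc = rng.uniform(oc_lo, oc_hi)
        h = int(round(hc * c))
        o = int(round(oc * c))
        if h < 0 or o < 0:
            continue
        if classify_vk((h / c, o / c if c else 0.0)) == name and o > 0:
            return c, h, o
    raise RuntimeError(
        f"could not draw an integer formula inside class box {name!r} "
        f"after {max_retries} attempts"
    )


def generate_formula_table(config: DOMSimConfig | None = None) -> pd.DataFrame:
    """Synthetic FT-ICR-MS formula-assignment table.

    Classes are drawn multinomially from the target shares; each formula's
    integer atom counts are rejection-sampled inside its class's H/C-O/C box
    so that classification closure is exact (the realized class of every row
    equals its intended class).  Heteroatoms follow the element-group mixture
    (N and S do not affect the Van Krevelen position); intensities are
    log-normal.
    """
    config = config or DOMSimConfig()
    rng = np.random.default_rng(config.seed)
    boxes = {name: box for box in DEFAULT_CLASS_BOXES for name in [box[0]]}
    labels = list(config.class_shares)
    probs = np.array([config.class_shares[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    groups = list(config.element_group_probs)
    gprobs = np.array([config.element_group_probs[g] for g in groups], dtype=float)
    gprobs = gprobs / gprobs.sum()

    drawn_classes = rng.choice(len(labels), size=config.n_formulas, p=probs)
    drawn_groups = rng.choice(len(groups), size=config.n_formulas, p=gprobs)
    rows = []
    for ci, gi in zip(drawn_classes, drawn_groups):
        label = labels[ci]
        c, h, o = _sample_formula_in_box(rng, boxes[label], config.c_range, config.max_retries)
        grp = groups[gi]
        n = int(rng.integers(1, 3)) if "N" in grp.replace("CHO", "", 1) else 0
        s = 1 if grp in ("CHOS", "CHONS") else 0
        rows.append(
            {"c": c, "h": h, "o": o, "n": n, "s": s,
             "relative_intensity": float(rng.lognormal(0.0, config.intensity_sigma)),
             "sample_id": config.sample_id, "intended_class": label}
        )
    return pd.DataFrame(rows)


def write_fixture_set(out_dir: str | Path, bmp_config: BMPSimConfig | None = None,
                      dom_config: DOMSimConfig | None = None) -> dict[str, Path]:
    """Materialize the standard fixture bundle as delimiter-separated files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = generate_bmp_dataset(bmp_config)
    paths = {}
    paths["gas_logs"] = out / "gas_logs.csv"
    sim.gas_logs.to_csv(paths["gas_logs"], index=False)
    meta_df = pd.DataFrame([dataclasses.asdict(m) for m in sim.channel_meta])
    paths["channel_meta"] = out / "channel_meta.csv"
    meta_df.to_csv(paths["channel_meta"], index=False)

    t = np.arange(0.0, 26.0)
    series = generate_substrate_series(10.0, 0.97, t, noise_cv=0.02,
                                       seed=sim.config.seed)
    paths["substrate_series"] = out / "substrate_series.csv"
    pd.DataFrame({"time_days": t, "concentration_g_l": series}).to_csv(
        paths["substrate_series"], index=False
    )

    dom = generate_formula_table(dom_config)
    paths["formulas"] = out / "formulas.csv"
    dom.to_csv(paths["formulas"], index=False)

    manifest = {
        "seed": sim.config.seed,
        "groups": [g.label for g in sim.config.groups],
        "true_models": {
            g.label: {"name": g.true_model.name, **g.true_model.params}
            for g in sim.config.groups
        },
    }
    paths["manifest"] = out / "fixture_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
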