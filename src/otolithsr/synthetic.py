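"""Synthetic otoliths with known life histories and a virtual LA-MC-ICP-MS.

This module is the ground-truth oracle for the rest of the package. It
generates, for each of the six life-history archetypes of an Arctic
whitefish cohort:

* a habitat trajectory (freshwater / estuarine / marine segments over age),
* water chemistry per segment (⁸⁷Sr/⁸⁶Sr and dissolved Sr from two
  end-member mixing between river water and seawater),
* otolith geometry (annuli placed on a von-Bertalanffy-like growth curve,
  so outer annuli condense the way old-fish otoliths do),
* the true core-to-edge profile the otolith records (instant equilibration
  with ambient water, optional maternally derived marine-like core zone,
  smearing by the 35 µm laser spot), and
* raw beam voltages at m/z 82–88 distorted by every effect the reduction
  chain removes: gas blank, CaCa⁺/CaAr⁺ interferences, the ⁸⁷Rb isobar,
  exponential-law mass fractionation, sensitivity/β drift and shot noise —
  plus SRM 987 bracketing standards on the same clock.

Freshwater end-members mimic a watershed whose streams run ~0.7103–0.7112
(natal/rearing reaches) against the global marine value 0.70918; estuarine
water is a seawater-dominated mixture, which is why its ratio sits within a
few 1e-5 of the GMV while its Sr concentration is intermediate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants as C
from .reduction import (RawAblationRun, StandardAcquisition, ValidationError)

HABITATS = ("freshwater", "estuarine", "marine")

TYPE_NAMES = {
    1: "early marine anadromous",
    2: "late freshwater anadromous",
    3: "late transitional anadromous",
    4: "semi-anadromous",
    5: "freshwater estuarine nonanadromous",
    6: "freshwater resident",
}


@dataclass(frozen=True)
class HabitatSegment:
    """One contiguous residence in a habitat, in age (years) coordinates."""

    age_start: float
    age_end: float
    habitat: str
    water_ratio: float
    water_sr: float

    def __post_init__(self) -> None:
        if self.age_start < 0 or self.age_end <= self.age_start:
            raise ValidationError("segment ages must satisfy 0 <= start < end")
        if self.habitat not in HABITATS:
            raise ValidationError(f"habitat must be one of {HABITATS}")
        if self.water_sr <= 0:
            raise ValidationError("water_sr must be positive")
        if self.habitat == "marine" and abs(self.water_ratio - C.GMV) > C.GMV_TOL:
            raise ValidationError("marine water_ratio must lie within the GMV band")


def validate_trajectory(segments: list[HabitatSegment]) -> None:
    """Check contiguity/non-overlap of a trajectory."""
    if not segments:
        raise ValidationError("trajectory has no segments")
    for a, b in zip(segments, segments[1:]):
        if not math.isclose(a.age_end, b.age_start, abs_tol=1e-9):
            raise ValidationError("trajectory segments must be contiguous")


def water_mixture(fw_ratio: float, fw_sr: float, sea_fraction: float,
                  sea_ratio: float = C.GMV,
                  sea_sr: float = C.SEAWATER_SR_MGL) -> tuple[float, float]:
    """Two-end-member conservative mixture of river water and seawater.

    The mixed ⁸⁷Sr/⁸⁶Sr is the Sr-concentration-weighted mean of the
    end-member ratios; the mixed Sr concentration is linear in the mixing
    fraction. Because seawater carries ~100× more Sr than river water, the
    mixture ratio converges on the GMV at quite small sea fractions.
    """
    if not 0.0 <= sea_fraction <= 1.0:
        raise ValidationError("sea_fraction must be in [0, 1]")
    if fw_sr <= 0:
        raise ValidationError("fw_sr must be positive")
    sr = (1.0 - sea_fraction) * fw_sr + sea_fraction * sea_sr
    ratio = ((1.0 - sea_fraction) * fw_sr * fw_ratio
             + sea_fraction * sea_sr * sea_ratio) / sr
    return ratio, sr


# ---------------------------------------------------------------------------
# generator settings and instrument model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the synthetic cohort.

    Water-chemistry pools mirror the watershed/ocean end-members the
    analysis assumes; entry-age distributions for the late-migrating
    anadromous types follow the observed migration-age table.
    """

    lifespan: float = 20.0
    core_to_edge_um: float = 2125.0     # 850 readings at 2.5 µm/reading
    lead_um: float = 50.0               # ablation starts this far before the core
    cadence_s: float = 0.5
    growth_k_range: tuple[float, float] = (0.22, 0.28)  # 1/yr
    maternal_um: float = 15.0           # marine-like core zone (types 1-4)
    #: otolith Sr (mg/kg) in fully marine water.
    marine_oto_sr: float = 2000.0
    #: power-law exponent mapping water Sr (mg/L) to otolith Sr (mg/kg).
    oto_sr_gamma: float = 0.274
    #: freshwater 87Sr/86Sr pools (natal reaches by strategy; rearing delta).
    fw_ratio_anadromous: tuple[float, float] = (0.7103, 0.7109)
    fw_ratio_nonanadromous: tuple[float, float] = (0.7110, 0.71125)
    fw_juvenile_delta: tuple[float, float] = (1e-4, 3e-4)
    #: freshwater dissolved Sr, mg/L.
    fw_sr_range: tuple[float, float] = (0.04, 0.2)
    #: sea fraction of estuarine water (rearing episodes / type-4 natal).
    estuary_fraction: tuple[float, float] = (0.10, 0.45)
    natal_estuary_fraction: tuple[float, float] = (0.35, 0.50)
    #: dilute low-ratio coastal streams feeding the type-4 estuary mixtures.
    fw_ratio_coastal: tuple[float, float] = (0.7095, 0.7105)
    fw_sr_coastal: tuple[float, float] = (0.03, 0.07)
    #: entry-age distributions for the late anadromous types.
    entry_ages_type2: tuple[tuple[int, ...], tuple[float, ...]] = (
        (1, 2, 3, 5), (10 / 14, 1 / 14, 2 / 14, 1 / 14))
    entry_ages_type3: tuple[tuple[int, ...], tuple[float, ...]] = (
        (1, 2), (5 / 9, 4 / 9))

    def __post_init__(self) -> None:
        if self.lifespan <= 1:
            raise ValidationError("lifespan must exceed 1 year")
        if self.cadence_s <= 0:
            raise ValidationError("cadence_s must be positive")


@dataclass(frozen=True)
class InstrumentModel:
    """Parameters of the virtual multi-collector instrument."""

    #: V at m/z 88 per mg/kg of otolith Sr; default solved so that the
    #: 12.26 V marine threshold corresponds to ~1700 mg/kg (and 6.13 V to
    #: ~850 mg/kg) through the FEBs-1 concentration standard.
    sensitivity: float = 14.82 / C.FEBS1_SR_MGKG
    blank_levels: dict = field(default_factory=lambda: {
        82: 0.004, 83: 0.004, 84: 0.005, 85: 0.003,
        86: 0.006, 87: 0.005, 88: 0.010})
    beta_iif: float = -0.5
    rb_level: float = 2e-4        # 85Rb beam as a fraction of the 88Sr beam
    dimer_amp: float = 0.002      # CaCa+ V at m/z 82
    argide_amp: float = 0.001     # CaAr+ V at m/z 83
    noise_sd: float = 1e-4        # relative SD per reading per mass
    drift_rate: float = 0.002     # fractional sensitivity change per hour
    beta_drift: float = 0.01      # beta change per hour
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValidationError("sensitivity must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if any(v < 0 for v in self.blank_levels.values()):
            raise ValidationError("blank levels must be non-negative")

    @staticmethod
    def ideal() -> "InstrumentModel":
        """A distortion-free instrument: raw ratios equal true ratios."""
        return InstrumentModel(
            blank_levels={m: 0.0 for m in C.CHANNELS}, beta_iif=0.0,
            rb_level=0.0, dimer_amp=0.0, argide_amp=0.0, noise_sd=0.0,
            drift_rate=0.0, beta_drift=0.0)


@dataclass(frozen=True)
class SyntheticOtolith:
    """A simulated otolith with full ground truth attached."""

    otolith_id: str
    trajectory: list
    annuli_um: np.ndarray
    core_to_edge_um: float
    core_offset_um: float          # ablation lead-in before the core
    true_profile: pd.DataFrame     # position_um, age, habitat, ratio, sr_mgkg, pure
    raw_run: RawAblationRun | None
    standards: list
    truth_label: int
    truth_entry_age: int | None

    def __post_init__(self) -> None:
        ann = np.asarray(self.annuli_um, float)
        if len(ann) and (np.any(np.diff(ann) <= 0)
                         or ann[0] <= 0 or ann[-1] >= self.core_to_edge_um):
            raise ValidationError(
                "annuli must be strictly increasing within (0, core_to_edge)")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _fresh(rng, lo_hi) -> tuple[float, float]:
    """Draw a freshwater end-member (ratio from pool, Sr from range)."""
    return float(rng.uniform(*lo_hi)), None


def make_trajectory(type_id: int, params: GeneratorParams | None = None,
                    seed: int = 0) -> list[HabitatSegment]:
    """Instantiate a habitat trajectory satisfying a life-history archetype.

    Types: 1 early marine anadromous (sea before age 1); 2 late freshwater
    anadromous (freshwater age-0, sea at age ≥ 1); 3 late transitional
    anadromous (fresh + estuarine age-0, sea at age ≥ 1); 4 semi-anadromous
    (estuarine from hatch, natal ratio at the GMV, alternating
    estuarine/marine); 5 freshwater–estuarine nonanadromous (never marine);
    6 freshwater resident (freshwater only).
    """
    if type_id not in TYPE_NAMES:
        raise ValidationError(
            f"unknown life-history type {type_id!r}; valid types are 1-6 "
            f"({', '.join(f'{k}={v}' for k, v in TYPE_NAMES.items())})")
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    L = p.lifespan
    segs: list[HabitatSegment] = []

    def fresh_seg(a0, a1, ratio):
        sr = float(rng.uniform(*p.fw_sr_range))
        return HabitatSegment(a0, a1, "freshwater", ratio, sr)

    def estuary_seg(a0, a1, frac_range, fw_ratio, fw_sr):
        f = float(rng.uniform(*frac_range))
        ratio, sr = water_mixture(fw_ratio, fw_sr, f)
        return HabitatSegment(a0, a1, "estuarine", ratio, sr)

    def marine_seg(a0, a1):
        return HabitatSegment(a0, a1, "marine", C.GMV, C.SEAWATER_SR_MGL)

    if type_id == 1:
        natal = float(rng.uniform(*p.fw_ratio_anadromous))
        juv = natal - float(rng.uniform(*p.fw_juvenile_delta))
        a1 = float(rng.uniform(0.15, 0.30))
        a2 = float(rng.uniform(0.45, 0.80))
        segs = [fresh_seg(0.0, a1, natal), fresh_seg(a1, a2, juv),
                marine_seg(a2, L)]
    elif type_id == 2:
        natal = float(rng.uniform(*p.fw_ratio_anadromous))
        juv = natal + float(rng.uniform(*p.fw_juvenile_delta))
        ages, probs = p.entry_ages_type2
        e = int(rng.choice(ages, p=probs))
        a1 = float(rng.uniform(0.15, 0.30))
        entry = e + float(rng.uniform(0.25, 0.75))
        segs = [fresh_seg(0.0, a1, natal), fresh_seg(a1, entry, juv),
                marine_seg(entry, L)]
    elif type_id == 3:
        natal = float(rng.uniform(*p.fw_ratio_anadromous))
        fw_sr = float(rng.uniform(*p.fw_sr_range))
        ages, probs = p.entry_ages_type3
        e = int(rng.choice(ages, p=probs))
        b = float(rng.uniform(0.25, 0.50))
        entry = e + float(rng.uniform(0.25, 0.75))
        segs = [fresh_seg(0.0, b, natal),
                estuary_seg(b, entry, p.estuary_fraction, natal, fw_sr),
                marine_seg(entry, L)]
    elif type_id == 4:
        fw_ratio = float(rng.uniform(*p.fw_ratio_coastal))
        fw_sr = float(rng.uniform(*p.fw_sr_coastal))
        a = float(rng.uniform(0.8, 1.5))
        segs = [estuary_seg(0.0, a, p.natal_estuary_fraction, fw_ratio, fw_sr)]
        marine = True
        while a < L:
            b = min(L, a + float(rng.uniform(0.5, 1.5)))
            segs.append(marine_seg(a, b) if marine else
                        estuary_seg(a, b, p.natal_estuary_fraction,
                                    fw_ratio, fw_sr))
            marine = not marine
            a = b
    elif type_id == 5:
        natal = float(rng.uniform(*p.fw_ratio_nonanadromous))
        juv = natal - float(rng.uniform(*p.fw_juvenile_delta))
        fw_sr = float(rng.uniform(*p.fw_sr_range))
        a1 = float(rng.uniform(0.15, 0.30))
        segs = [fresh_seg(0.0, a1, natal), fresh_seg(a1, 2.0, juv)]
        a, est = 2.0, True
        while a < L:
            b = min(L, a + float(rng.uniform(1.0, 3.0)))
            segs.append(estuary_seg(a, b, p.estuary_fraction, natal, fw_sr)
                        if est else fresh_seg(a, b, juv))
            est = not est
            a = b
    else:  # type 6
        natal = float(rng.uniform(*p.fw_ratio_nonanadromous))
        segs = [fresh_seg(0.0, L, natal)]

    validate_trajectory(segs)
    return segs


def trajectory_entry_age(segments: list[HabitatSegment]) -> int | None:
    """Floor of the age at the first marine segment, or None."""
    for s in segments:
        if s.habitat == "marine":
            return int(math.floor(s.age_start))
    return None


# ---------------------------------------------------------------------------
# geometry and truth profile
# ---------------------------------------------------------------------------

def _growth(params: GeneratorParams, rng) -> tuple[float, float]:
    """(K, R_inf) of the decaying-increment growth curve r(a)=R(1-e^{-Ka})."""
    k = float(rng.uniform(*params.growth_k_range))
    r_inf = params.core_to_edge_um / (1.0 - math.exp(-k * params.lifespan))
    return k, r_inf


def _age_at(r_um: np.ndarray, k: float, r_inf: float) -> np.ndarray:
    x = np.clip(1.0 - np.asarray(r_um, float) / r_inf, 1e-12, 1.0)
    return -np.log(x) / k


def _segment_lookup(segments, ages):
    """Per-age habitat/ratio/sr arrays (last segment owns its end age)."""
    starts = np.array([s.age_start for s in segments])
    idx = np.clip(np.searchsorted(starts, ages, side="right") - 1,
                  0, len(segments) - 1)
    ratio = np.array([segments[i].water_ratio for i in idx])
    sr = np.array([segments[i].water_sr for i in idx])
    habitat = np.array([segments[i].habitat for i in idx], dtype=object)
    return habitat, ratio, sr


def _oto_sr(water_sr: np.ndarray, p: GeneratorParams) -> np.ndarray:
    return p.marine_oto_sr * (np.asarray(water_sr) / C.SEAWATER_SR_MGL) ** p.oto_sr_gamma


def make_otolith(type_id: int, params: GeneratorParams | None = None,
                 inst: InstrumentModel | None = None, seed: int = 0,
                 otolith_id: str | None = None) -> SyntheticOtolith:
    """Generate one synthetic otolith: trajectory, truth, and raw signals."""
    p = params or GeneratorParams()
    inst = inst or InstrumentModel()
    rng = np.random.default_rng(seed)
    traj = make_trajectory(type_id, p, seed=int(rng.integers(2 ** 31)))
    k, r_inf = _growth(p, rng)
    ann = np.arange(1, int(p.lifespan) + 1, dtype=float)
    ann_um = r_inf * (1.0 - np.exp(-k * ann))
    ann_um = ann_um[ann_um < p.core_to_edge_um - 1.0]

    um_per_reading = p.cadence_s * C.SCAN_SPEED_UM_S
    n_total = int(round((p.lead_um + p.core_to_edge_um) / um_per_reading)) + 1
    d = np.arange(n_total) * um_per_reading          # from ablation start
    x = d - p.lead_um                                # signed, 0 at the core
    ages = _age_at(np.abs(x), k, r_inf)              # mirror across the core
    habitat, w_ratio, w_sr = _segment_lookup(traj, ages)
    ratio = w_ratio.astype(float)
    sr = _oto_sr(w_sr, p)

    maternal = np.abs(x) < p.maternal_um
    if type_id in (1, 2, 3, 4):
        # offspring of a sea-run female: marine-like chemistry at the core
        ratio[maternal] = C.GMV
        sr[maternal] = p.marine_oto_sr
    else:
        maternal = np.zeros_like(maternal)

    # laser-spot smearing: the plasma sees a Sr-weighted moving average
    n_spot = max(1, int(round(C.SPOT_UM / um_per_reading)))
    kernel = np.ones(n_spot) / n_spot
    norm = np.convolve(np.ones_like(sr), kernel, mode="same")
    sr_s = np.convolve(sr, kernel, mode="same") / norm
    ratio_s = np.convolve(sr * ratio, kernel, mode="same") / norm / sr_s

    # a reading is "pure" when the whole spot sits in one habitat zone
    zone = pd.factorize(pd.Series(habitat).astype(str)
                        + np.where(maternal, "|m", ""))[0]
    half = n_spot // 2
    pure = np.array([np.ptp(zone[max(0, i - half):i + half + 1]) == 0
                     for i in range(n_total)])

    in_core = x >= -1e-9
    true_profile = pd.DataFrame({
        "position_um": x[in_core],
        "age": np.where(np.abs(x[in_core]) < 1e-9, 0.0, ages[in_core]),
        "habitat": habitat[in_core],
        "ratio": ratio_s[in_core],
        "sr_mgkg": sr_s[in_core],
        "pure": pure[in_core],
    }).reset_index(drop=True)

    oid = otolith_id or f"type{type_id}_seed{seed}"
    oto = SyntheticOtolith(
        otolith_id=oid, trajectory=traj, annuli_um=ann_um,
        core_to_edge_um=p.core_to_edge_um, core_offset_um=p.lead_um,
        true_profile=true_profile, raw_run=None, standards=[],
        truth_label=type_id, truth_entry_age=trajectory_entry_age(traj))
    run, standards = simulate_ablation_run(
        oto, inst, seed=int(rng.integers(2 ** 31)),
        _signal=(ratio_s, sr_s), _cadence=p.cadence_s)
    return replace(oto, raw_run=run, standards=standards)


# ---------------------------------------------------------------------------
# instrument simulation
# ---------------------------------------------------------------------------

def simulate_ablation_run(oto: SyntheticOtolith, inst: InstrumentModel,
                          seed: int = 0, _signal=None, _cadence=None,
                          ) -> tuple[RawAblationRun, list[StandardAcquisition]]:
    """Turn a true profile into raw beam voltages plus bracketing standards.

    A 30 s gas-blank phase precedes ablation; ablation readings advance at
    ``cadence × 5 µm/s``. Per-mass gains follow the exponential law
    ``g(m) = (m/m86)**(−β(t))`` so measured ratios are
    ``R_true · (m_num/m_den)**(−β)``; ⁸⁵Rb/⁸⁷Rb ride along with natural
    abundances; CaCa⁺/CaAr⁺ add their isotopologue patterns at m/z 82–88;
    blanks and multiplicative Gaussian noise finish the job. SRM 987
    standards are emitted every 30 simulated minutes with the same β(t).
    """
    if _signal is not None:
        ratio, sr = _signal
    else:
        tp = oto.true_profile
        ratio = tp["ratio"].to_numpy(float)
        sr = tp["sr_mgkg"].to_numpy(float)
    cadence = _cadence if _cadence is not None else 0.5
    if cadence <= 0:
        raise ValidationError("cadence must be positive")
    if len(ratio) == 0:
        raise ValidationError("empty trajectory/profile: nothing to ablate")
    rng = np.random.default_rng(seed)

    n_blank = int(round(C.BLANK_WINDOW_S / cadence))
    t_blank = (np.arange(n_blank) + 1) * cadence
    t_abl = C.BLANK_WINDOW_S + (np.arange(len(ratio)) + 1) * cadence
    t_all = np.concatenate([t_blank, t_abl])

    beta_t = inst.beta_iif + inst.beta_drift * t_abl / 3600.0
    sens_t = inst.sensitivity * (1.0 + inst.drift_rate * t_abl / 3600.0)
    ab = C.SR_ABUNDANCE

    def gain(mass_u: float) -> np.ndarray:
        return (mass_u / C.ATOMIC_MASS[86]) ** (-beta_t)

    v88_pre = sens_t * sr
    sig = {m: np.zeros_like(v88_pre) for m in C.CHANNELS}
    sig[88] = v88_pre * gain(C.ATOMIC_MASS[88])
    sig[86] = v88_pre * (ab[86] / ab[88]) * gain(C.ATOMIC_MASS[86])
    sig[87] = v88_pre * (ab[86] / ab[88]) * ratio * gain(C.ATOMIC_MASS[87])
    sig[84] = v88_pre * (ab[84] / ab[88]) * gain(C.ATOMIC_MASS[84])
    if inst.rb_level > 0:
        v85_rb = inst.rb_level * v88_pre
        sig[85] = sig[85] + v85_rb * gain(C.ATOMIC_MASS[85])
        sig[87] = sig[87] + v85_rb * C.RB_87_85 * gain(C.MASS_RB87)

    from .reduction import ReductionConfig
    dpat, apat = ReductionConfig().interference_matrix()
    scale = 1.0 + inst.drift_rate * t_abl / 3600.0
    for m in C.CHANNELS:
        sig[m] = sig[m] + scale * (inst.dimer_amp * dpat[m]
                                   + inst.argide_amp * apat[m])

    rows = {}
    for m in C.CHANNELS:
        blank = np.full(n_blank, inst.blank_levels.get(m, 0.0))
        v = np.concatenate([blank, sig[m] + inst.blank_levels.get(m, 0.0)])
        if inst.noise_sd > 0:
            v = v * (1.0 + inst.noise_sd * rng.standard_normal(len(v)))
        rows[f"v{m}"] = v
    data = pd.DataFrame({
        "time_s": t_all,
        "phase": ["blank"] * n_blank + ["ablation"] * len(ratio),
        **rows})

    # bracketing standards on the same clock, every 30 simulated minutes
    std_times = [0.0]
    while std_times[-1] < t_all[-1]:
        std_times.append(std_times[-1] + 1800.0)
    standards = []
    mass_frac = (C.ATOMIC_MASS[87] / C.ATOMIC_MASS[86])
    for ts in std_times:
        beta_s = inst.beta_iif + inst.beta_drift * ts / 3600.0
        meas = C.SRM987_RATIO * mass_frac ** (-beta_s)
        if inst.noise_sd > 0:
            meas *= 1.0 + 0.1 * inst.noise_sd * rng.standard_normal()
        standards.append(StandardAcquisition(ts, float(meas)))

    meta = {
        "otolith_id": oto.otolith_id,
        "seed": int(seed),
        "core_offset_um": float(oto.core_offset_um),
        "core_to_edge_um": float(oto.core_to_edge_um),
        "febs1_mean_v88": float(inst.sensitivity * C.FEBS1_SR_MGKG
                                * (C.ATOMIC_MASS[88] / C.ATOMIC_MASS[86])
                                ** (-inst.beta_iif)),
        "truth_label": int(oto.truth_label),
    }
    run = RawAblationRun(data=data, cadence_s=cadence, meta=meta)
    return run, standards


def simulate_cohort(n_per_type: int, inst: InstrumentModel | None = None,
                    seed: int = 0, params: GeneratorParams | None = None,
                    ) -> list[SyntheticOtolith]:
    """Simulate ``6 × n_per_type`` otoliths, one batch per life-history type.

    Deterministic for a fixed seed: every otolith's randomness derives from
    a spawned child of the root seed sequence.
    """
    if n_per_type < 1:
        raise ValidationError("n_per_type must be >= 1")
    inst = inst or InstrumentModel()
    params = params or GeneratorParams()
    root = np.random.SeedSequence(seed)
    otoliths = []
    children = root.spawn(6 * n_per_type)
    i = 0
    for type_id in range(1, 7):
        for j in range(n_per_type):
            child_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            otoliths.append(make_otolith(
                type_id, params, inst, seed=child_seed,
                otolith_id=f"type{type_id}_{j:02d}"))
            i += 1
    return otoliths
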