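"""Synthetic longitudinal cohorts with ground-truth progression labels.

The generator emulates the structure the analysis assumes: a baseline
cluster of 2–4 repeat tests within 4 months, follow-up visits at roughly
6-month intervals out to a 12–59-month series span, per-metric Gaussian
test–retest noise around an eye-level true baseline, and linear true change.

Definitely-progressing (DP) eyes receive topographically concordant
worsening: a temporal-inferior or temporal-superior cpRNFL sector, the
matching GCL region(s), and the corresponding visual-field hemifield MD
all worsen together, with attenuated change in the global metrics that
average over the damaged sector.  A fraction of the remaining patient
eyes progress in structure only, at half rate, so the cohort also contains
harder, discordant cases.

Visual-field baseline distributions default to the study-population
summary statistics (healthy controls: 24-2 MD −1.25 ± 2.03 dB,
PSD 1.78 ± 0.77 dB; patients: MD −1.58 ± 1.96 dB, PSD 2.82 ± 1.92 dB).
OCT baseline levels and all test–retest noise SDs are generator
parameters chosen as typical instrument values; nothing downstream
depends on their specific values.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortDataset, EyeSeries, Visit, years_between
from .metrics import Direction, Modality, builtin_metrics, get_metric

BASE_DATE = dt.date(2020, 1, 6)

# Eye-level baseline distributions, (mean, sd) per metric per group.
# Thicknesses in µm, MD/PSD in dB, VFI in %.
_HC_OCT_BASE = {
    "G_small": (97.0, 9.0), "T_small": (74.0, 11.0), "TI_small": (145.0, 17.0),
    "TS_small": (135.0, 17.0), "N_small": (76.0, 12.0), "NI_small": (112.0, 20.0),
    "NS_small": (106.0, 20.0),
    "G_MRW": (330.0, 50.0), "T_MRW": (225.0, 40.0), "TI_MRW": (310.0, 50.0),
    "TS_MRW": (305.0, 50.0), "N_MRW": (350.0, 55.0), "NI_MRW": (380.0, 55.0),
    "NS_MRW": (365.0, 55.0),
    "G_GCL": (38.0, 3.5), "I_GCL": (37.0, 3.5), "TI_GCL": (40.0, 3.5),
    "NI_GCL": (40.0, 3.5), "S_GCL": (37.0, 3.5), "TS_GCL": (40.0, 3.5),
    "NS_GCL": (40.0, 3.5),
}
_HC_VF_BASE = {
    # 24-2 MD/PSD are the published healthy-control summary statistics.
    "MD_24": (-1.25, 2.03), "supMD_24": (-1.2, 2.0), "infMD_24": (-1.2, 2.0),
    "PSD_24": (1.78, 0.77), "VFI_24": (98.5, 1.5),
    "MD_10": (-1.0, 1.8), "supMD_10": (-1.0, 1.8), "infMD_10": (-1.0, 1.8),
    "PSD_10": (1.6, 0.8),
}
_PATIENT_VF_BASE = {
    # 24-2 MD/PSD are the published patient/suspect summary statistics.
    "MD_24": (-1.58, 1.96), "supMD_24": (-1.6, 2.0), "infMD_24": (-1.6, 2.0),
    "PSD_24": (2.82, 1.92), "VFI_24": (97.0, 2.5),
    "MD_10": (-1.4, 2.0), "supMD_10": (-1.4, 2.0), "infMD_10": (-1.4, 2.0),
    "PSD_10": (2.2, 1.4),
}


def _default_baselines() -> dict[str, dict[str, tuple[float, float]]]:
    hc = dict(_HC_OCT_BASE) | dict(_HC_VF_BASE)
    # Patients/suspects: early damage, thicknesses ~7% thinner, more spread.
    pat = {m: (mu * 0.93, sd * 1.15) for m, (mu, sd) in _HC_OCT_BASE.items()}
    pat |= dict(_PATIENT_VF_BASE)
    return {"HC": hc, "patient": pat, "suspect": pat}


def _default_noise_sd() -> dict[str, float]:
    """Test–retest measurement SD per metric (generator parameters)."""
    sd = {}
    for name, m in builtin_metrics().items():
        if m.modality == Modality.CPRNFL:
            sd[name] = 1.5 if m.sector == "G" else 2.5
        elif m.modality == Modality.BMO_MRW:
            sd[name] = 6.0 if m.sector == "G" else 9.0
        elif m.modality == Modality.GCL:
            sd[name] = 1.0 if m.sector == "G" else 1.3
        elif name.startswith("PSD"):
            sd[name] = 0.6
        elif name.startswith("VFI"):
            sd[name] = 1.3
        else:  # MD and hemifield MD
            sd[name] = 1.0
    return sd


# True worsening rates (units/yr) injected into DP eyes, keyed by role.
DEFAULT_DP_RATE_PARAMS: dict[str, float] = {
    "cp_sector": -2.5,    # driven cpRNFL sector, µm/yr
    "cp_global": -1.2,    # G_small, µm/yr
    "mrw_sector": -2.5,   # matching BMO-MRW sector, µm/yr
    "gcl_sector": -1.5,   # matching GCL region(s), µm/yr
    "gcl_global": -0.8,   # G_GCL, µm/yr
    "md_hemi": -0.8,      # matching hemifield MD, dB/yr
    "md_global": -0.5,    # MD_24 / MD_10, dB/yr
    "vfi_global": -1.0,   # VFI_24, %/yr
    "psd_global": 0.3,    # PSD rises with localized damage, dB/yr
}

# Topographic concordance map: sectoral damage in the inferior (superior)
# retina is paired with the hemifield MD metric the instrument exports
# under the matching label.
_HEMIFIELDS = {
    "inferior": {
        "cp": "TI_small", "mrw": "TI_MRW", "gcl": ("TI_GCL", "I_GCL"),
        "md": ("infMD_24", "infMD_10"),
    },
    "superior": {
        "cp": "TS_small", "mrw": "TS_MRW", "gcl": ("TS_GCL", "S_GCL"),
        "md": ("supMD_24", "supMD_10"),
    },
}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the study conditions: 30 healthy controls and
    91 patient/suspect eyes of which 17 are definitely progressing;
    follow-up spans 12–59 months; 2–4 baseline tests within 4 months
    then ~6-month visit intervals; and a 176-eye test–retest set.
    """

    n_hc: int = 30
    n_patients: int = 91          # patients + suspects combined
    n_suspects: int = 37          # labelled "suspect" within n_patients
    n_dp: int = 17                # definitely-progressing subset of patients
    followup_months_range: tuple[float, float] = (12.0, 59.0)
    baseline_repeats_range: tuple[int, int] = (2, 4)
    baseline_window_days: int = 120
    visit_interval_months: float = 6.0
    visit_jitter_days: int = 21
    frac_nondp_progressing: float = 0.3
    nondp_rate_scale: float = 0.5
    unreliable_visit_frac: float = 0.02
    patient_variance_inflation: float = 1.0
    metrics: tuple[str, ...] = field(
        default_factory=lambda: tuple(builtin_metrics())
    )
    baseline_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_baselines
    )
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    dp_rate_params: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DP_RATE_PARAMS)
    )
    n_retest_eyes: int = 176
    n_retest_hc: int = 30
    retest_tests_range: tuple[int, int] = (2, 4)
    retest_within_60d_frac: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_dp > self.n_patients:
            raise ValueError("n_dp must not exceed n_patients")
        if self.n_suspects > self.n_patients:
            raise ValueError("n_suspects must not exceed n_patients")
        lo, hi = self.followup_months_range
        if not (12.0 <= lo <= hi <= 59.0):
            raise ValueError("followup_months_range must lie within (12, 59) months")
        for m in self.metrics:
            get_metric(m)
            if self.noise_sd[m] < 0:
                raise ValueError(f"negative noise_sd for {m}")
            for g in ("HC", "patient", "suspect"):
                if self.baseline_stats[g][m][1] <= 0:
                    raise ValueError(f"non-positive baseline sd for {g}/{m}")


@dataclass
class GroundTruth:
    """Per-eye true status and per-metric true rates of change (units/yr)."""

    status: dict[str, str]                    # eye_id -> stable|progressing|dp
    rates: dict[str, dict[str, float]]        # eye_id -> metric -> rate

    def rate(self, eye_id: str, metric: str) -> float:
        return self.rates.get(eye_id, {}).get(metric, 0.0)


def _eye_rng(seed: int, stream: str, index: int) -> np.random.Generator:
    """Deterministic per-eye substream; adding eyes never shifts earlier ones."""
    key = zlib.crc32(stream.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key, index))
    return np.random.default_rng(ss)


def _dp_rates(cfg: GeneratorConfig, hemifield: str) -> dict[str, float]:
    p = cfg.dp_rate_params
    hf = _HEMIFIELDS[hemifield]
    rates = {
        hf["cp"]: p["cp_sector"],
        hf["mrw"]: p["mrw_sector"],
        "G_small": p["cp_global"],
        "G_GCL": p["gcl_global"],
        "MD_24": p["md_global"],
        "MD_10": p["md_global"],
        "VFI_24": p["vfi_global"],
        "PSD_24": p["psd_global"],
        "PSD_10": p["psd_global"],
    }
    for g in hf["gcl"]:
        rates[g] = p["gcl_sector"]
    for m in hf["md"]:
        rates[m] = p["md_hemi"]
    return {m: r for m, r in rates.items() if m in cfg.metrics}


def _nondp_rates(cfg: GeneratorConfig, hemifield: str) -> dict[str, float]:
    """Structure-only progression at reduced rate (discordant case)."""
    p = cfg.dp_rate_params
    hf = _HEMIFIELDS[hemifield]
    s = cfg.nondp_rate_scale
    rates = {
        hf["cp"]: p["cp_sector"] * s,
        "G_small": p["cp_global"] * s,
        hf["gcl"][0]: p["gcl_sector"] * s,
    }
    return {m: r for m, r in rates.items() if m in cfg.metrics}


def _schedule_days(rng: np.random.Generator, cfg: GeneratorConfig) -> list[int]:
    """Visit offsets in days: baseline repeats then ~6-month follow-ups."""
    k = int(rng.integers(cfg.baseline_repeats_range[0], cfg.baseline_repeats_range[1] + 1))
    days = {0}
    while len(days) < k:
        days.add(int(rng.uniform(10, cfg.baseline_window_days)))
    span_days = rng.uniform(*cfg.followup_months_range) * 30.4375
    step = cfg.visit_interval_months * 30.4375
    t = step
    while t <= span_days + 1:
        d = int(t + rng.integers(-cfg.visit_jitter_days, cfg.visit_jitter_days + 1))
        if d > max(days):
            days.add(d)
        t += step
    out = sorted(days)
    # Keep the series span inside the study's eligibility window (>= 1 year).
    if out[-1] < 366:
        out[-1] = 366 + int(rng.integers(0, 14))
    return out


def _plausibility_clip(metric: str, value: float) -> float:
    m = get_metric(metric)
    if m.units == "µm":
        return max(value, 1.0)
    if m.name.startswith("VFI"):
        return min(max(value, 0.0), 100.0)
    if m.name.startswith("PSD"):
        return max(value, 0.0)
    return value


def _reliability(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[float, float]:
    if rng.uniform() < cfg.unreliable_visit_frac:
        return float(rng.uniform(16.0, 40.0)), float(rng.uniform(0.0, 30.0))
    return float(rng.uniform(0.0, 12.0)), float(rng.uniform(0.0, 25.0))


def _make_series(
    eye_id: str,
    group: str,
    dp_label: str,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    rates: dict[str, float],
    days: list[int],
) -> EyeSeries:
    infl = cfg.patient_variance_inflation if group != "HC" else 1.0
    base = {}
    for m in cfg.metrics:
        mu, sd = cfg.baseline_stats[group][m]
        base[m] = rng.normal(mu, sd)
    visits = []
    for d in days:
        t = d / 365.25
        vals = {}
        for m in cfg.metrics:
            noise = rng.normal(0.0, cfg.noise_sd[m] * infl) if cfg.noise_sd[m] > 0 else 0.0
            vals[m] = _plausibility_clip(m, base[m] + rates.get(m, 0.0) * t + noise)
        fp, fl = _reliability(rng, cfg)
        visits.append(
            Visit(BASE_DATE + dt.timedelta(days=d), vals, fp, fl)
        )
    return EyeSeries(eye_id, group, dp_label, visits)


def generate_cohort(cfg: GeneratorConfig) -> tuple[CohortDataset, GroundTruth]:
    """Simulate a longitudinal study cohort with known ground truth.

    Deterministic for a given ``cfg.seed``; each eye draws from its own
    RNG substream so changing group sizes never reshuffles other eyes.
    """
    cfg.validate()
    eyes: list[EyeSeries] = []
    status: dict[str, str] = {}
    truth_rates: dict[str, dict[str, float]] = {}

    for i in range(cfg.n_hc):
        rng = _eye_rng(cfg.seed, "hc", i)
        eye_id = f"HC_{i:04d}"
        days = _schedule_days(rng, cfg)
        eyes.append(_make_series(eye_id, "HC", "not_DP", rng, cfg, {}, days))
        status[eye_id] = "stable"
        truth_rates[eye_id] = {}

    for i in range(cfg.n_patients):
        rng = _eye_rng(cfg.seed, "pt", i)
        group = "suspect" if i >= cfg.n_patients - cfg.n_suspects else "patient"
        is_dp = i < cfg.n_dp
        eye_id = f"{'S' if group == 'suspect' else 'P'}_{i:04d}"
        hemifield = "inferior" if rng.uniform() < 0.5 else "superior"
        if is_dp:
            rates = _dp_rates(cfg, hemifield)
            st, dp_label = "dp", "DP"
        elif rng.uniform() < cfg.frac_nondp_progressing:
            rates = _nondp_rates(cfg, hemifield)
            st, dp_label = "progressing", "not_DP"
        else:
            rates, st, dp_label = {}, "stable", "not_DP"
        days = _schedule_days(rng, cfg)
        eyes.append(_make_series(eye_id, group, dp_label, rng, cfg, rates, days))
        status[eye_id] = st
        truth_rates[eye_id] = rates

    cohort = CohortDataset(eyes, provenance=f"synthetic(seed={cfg.seed})")
    return cohort, GroundTruth(status, truth_rates)


def generate_test_retest_set(cfg: GeneratorConfig) -> CohortDataset:
    """Simulate the short-term test–retest dataset: 2–4 tests within 4 months.

    True rates are forced to zero, so all within-eye variation is
    measurement noise — the assumption behind the variability thresholds.
    Most repeat tests fall within 60 days of the first, the remainder out
    to the 4-month limit.
    """
    cfg.validate()
    eyes = []
    for i in range(cfg.n_retest_eyes):
        rng = _eye_rng(cfg.seed, "retest", i)
        group = "HC" if i < cfg.n_retest_hc else "patient"
        eye_id = f"RT_{i:04d}"
        k = int(rng.integers(cfg.retest_tests_range[0], cfg.retest_tests_range[1] + 1))
        days = {0}
        while len(days) < k:
            if rng.uniform() < cfg.retest_within_60d_frac:
                days.add(int(rng.uniform(5, 60)))
            else:
                days.add(int(rng.uniform(60, cfg.baseline_window_days)))
        eyes.append(
            _make_series(eye_id, group, "not_DP" if group != "HC" else "not_DP",
                         rng, cfg, {}, sorted(days))
        )
    return CohortDataset(eyes, provenance=f"synthetic_retest(seed={cfg.seed})")


def inject_progression(series: EyeSeries, rates: dict[str, float]) -> EyeSeries:
    """Add linear true change (``rate`` units/yr per metric) to a series."""
    if not series.visits:
        return replace(series, visits=[])
    t0 = series.visits[0].date
    visits = []
    for v in series.visits:
        t = years_between(t0, v.date)
        vals = {
            m: x + rates.get(m, 0.0) * t for m, x in v.values.items()
        }
        visits.append(Visit(v.date, vals, v.vf_fp_rate_pct, v.vf_fixation_loss_pct))
    return EyeSeries(series.eye_id, series.group, series.dp_label, visits)


def truth_to_frame(truth: GroundTruth):
    """Ground truth as a tidy DataFrame (one row per eye/metric rate, plus status)."""
    import pandas as pd

    rows = []
    for eye_id, st in truth.status.items():
        rates = truth.rates.get(eye_id, {})
        if rates:
            for m, r in sorted(rates.items()):
                rows.append({"eye_id": eye_id, "status": st, "metric": m, "rate_per_year": r})
        else:
            rows.append({"eye_id": eye_id, "status": st, "metric": "", "rate_per_year": 0.0})
    return pd.DataFrame(rows, columns=["eye_id", "status", "metric", "rate_per_year"])
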