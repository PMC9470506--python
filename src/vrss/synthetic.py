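"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a VR-learning cohort of undergraduate medical
students: a 36 % simulator-sickness-positive fraction, three 5-minute HRV
epochs per participant (pre-learning baseline, minutes 0–5 and minutes 6–10
of the video), SSQ/NASA-TLX/Mini-CEX questionnaire responses, and the
cross-variable dependence that the downstream correlation screen and
mediation model are meant to detect.

Physiology: an RR tachogram is built as a mean RR interval modulated by one
sinusoid per spectral band, placed at the band's geometric-centre frequency,
so that a sinusoid of amplitude A (ms) contributes the closed-form A^2/2
(ms^2) to its band's power — the oracle used throughout the test suite.  An
optional broadband white term adds ``noise_fraction`` x (vlf+lf+hf) of
extra variance spread over the whole spectrum.

Dependence: a Gaussian copula over five latent variables — sickness
severity, the late-epoch VLF shift, physical demand, frustration, and the
physical-examination score — with configurable pairwise rank correlations.
Ordinal instrument values are produced by thresholding the latent normals at
quantiles chosen to reproduce the group medians/IQRs the instruments show in
this population; simulator-sickness-negative participants have all 16 SSQ
ratings identically zero.

One global seed fans out through ``numpy.random.SeedSequence`` to
per-participant substreams, so enlarging a cohort never perturbs existing
participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as ss

from .errors import InfeasibleCorrelationError, InvalidParameterError
from .hrv import RRSeries, ECGRecord
from .instruments import SSQ_SYMPTOMS, TLX_SUBSCALES, MINICEX_ITEMS, score_ssq

EPOCH_LABELS = ("baseline", "t0_5", "t6_10")
EPOCH_WINDOWS = {"baseline": (0.0, 300.0), "t0_5": (300.0, 600.0),
                 "t6_10": (600.0, 900.0)}

#: geometric-centre frequency of each band (Hz)
BAND_CENTRES = {
    "vlf": float(np.sqrt(0.003 * 0.04)),   # ~0.01095
    "lf": float(np.sqrt(0.04 * 0.15)),     # ~0.07746
    "hf": float(np.sqrt(0.15 * 0.4)),      # ~0.24495
}

LATENTS = ("ss_severity", "vlf_shift", "physical_demand", "frustration",
           "physical_exam")

DEFAULT_EFFECT_SIZES = {
    ("ss_severity", "vlf_shift"): 0.56,
    ("ss_severity", "physical_demand"): 0.54,
    ("ss_severity", "frustration"): 0.58,
    ("ss_severity", "physical_exam"): -0.50,
    ("vlf_shift", "physical_exam"): -0.48,
    ("vlf_shift", "physical_demand"): 0.30,
    ("vlf_shift", "frustration"): 0.30,
    ("physical_demand", "frustration"): 0.50,
    ("physical_demand", "physical_exam"): -0.30,
    ("frustration", "physical_exam"): -0.35,
}

#: four most frequent sickness symptoms in this population, heavier weights
SYMPTOM_WEIGHTS = {
    "dizzy_eyes_open": 6.0, "difficulty_focusing": 5.0,
    "difficulty_concentrating": 5.0, "vertigo": 1.0,
}

#: video motion-degree timeline sampled at the six report minutes
MOTION_DEGREES_BY_MINUTE = {0: 0, 2: 0, 4: 0, 6: 1, 8: 2, 10: 1}


@dataclass
class AutonomicProfile:
    """Target HRV structure for one epoch: mean RR plus per-band powers."""

    mean_rr: float = 800.0          # ms
    vlf_power: float = 1000.0       # ms^2
    lf_power: float = 900.0         # ms^2
    hf_power: float = 700.0         # ms^2
    drift: float = 0.0              # ms per minute, linear trend
    noise_fraction: float = 0.0     # broadband extra variance as a fraction
                                    # of vlf+lf+hf

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise InvalidParameterError("mean_rr must be positive")
        for name in ("vlf_power", "lf_power", "hf_power"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite and >= 0")
        if self.noise_fraction < 0:
            raise InvalidParameterError("noise_fraction must be >= 0")

    @property
    def band_total(self) -> float:
        return self.vlf_power + self.lf_power + self.hf_power


def _default_epoch_profiles() -> dict:
    """Group-level band-power targets per sickness status and epoch.

    Values are the per-group central tendencies observed in a 28-student
    360-degree-VR cohort: sickness-positive students show markedly higher
    late-epoch VLF power.
    """
    return {
        "ss_positive": {
            "baseline": AutonomicProfile(824, 2879, 1938, 924, noise_fraction=0.1),
            "t0_5": AutonomicProfile(822, 1526, 1250, 821, noise_fraction=0.1),
            "t6_10": AutonomicProfile(827, 2050, 1325, 927, noise_fraction=0.1),
        },
        "ss_negative": {
            "baseline": AutonomicProfile(784, 902, 1315, 798, noise_fraction=0.1),
            "t0_5": AutonomicProfile(797, 964, 856, 637, noise_fraction=0.1),
            "t6_10": AutonomicProfile(787, 978, 991, 524, noise_fraction=0.1),
        },
    }


def _normalize_pair(key) -> tuple[str, str]:
    if isinstance(key, str):
        a, b = key.split(":")
    else:
        a, b = key
    if a not in LATENTS or b not in LATENTS or a == b:
        raise InvalidParameterError(f"unknown latent pair {key!r}")
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass
class CohortConfig:
    """Everything the cohort generator needs, validated at construction."""

    n_participants: int = 28
    n_ss_positive: int = 10
    epoch_profiles: dict = field(default_factory=_default_epoch_profiles)
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    #: within-group log-scale SD of the 6-10 min VLF power
    vlf_sigma: float = 0.8
    #: share of that dispersion carried by the vlf_shift latent (the rest is
    #: idiosyncratic); together with the status-median separation these
    #: defaults realise the default configured rank correlation with SSQ
    vlf_latent_share: float = 0.5
    #: log-scale SD of the independent jitter on all other band powers
    band_sigma: float = 0.3
    age_probs: dict = field(default_factory=lambda: {23: 0.20, 24: 0.45,
                                                     25: 0.25, 26: 0.10})
    p_female: float = 8 / 28
    generate_rr: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_ss_positive <= self.n_participants:
            raise InvalidParameterError(
                "need 0 <= n_ss_positive <= n_participants")
        self.effect_sizes = {_normalize_pair(k): float(v)
                             for k, v in self.effect_sizes.items()}
        for pair, r in self.effect_sizes.items():
            if not -1.0 <= r <= 1.0:
                raise InfeasibleCorrelationError(
                    f"correlation for {pair} is {r}; must be in [-1, 1]")
        self.latent_corr()  # raises if infeasible

    def latent_corr(self) -> np.ndarray:
        """Implied latent correlation matrix; must be positive semi-definite."""
        k = len(LATENTS)
        R = np.eye(k)
        idx = {name: i for i, name in enumerate(LATENTS)}
        for (a, b), r in self.effect_sizes.items():
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
        if np.linalg.eigvalsh(R).min() < -1e-10:
            # find a single pair whose removal restores feasibility, if any
            for pair in self.effect_sizes:
                R2 = R.copy()
                i, j = idx[pair[0]], idx[pair[1]]
                R2[i, j] = R2[j, i] = 0.0
                if np.linalg.eigvalsh(R2).min() >= -1e-10:
                    raise InfeasibleCorrelationError(
                        f"correlation matrix not positive semi-definite; "
                        f"pair {pair} makes it infeasible")
            raise InfeasibleCorrelationError(
                "correlation matrix not positive semi-definite")
        return R

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["epoch_profiles"] = {
            status: {ep: asdict(prof) for ep, prof in eps.items()}
            for status, eps in self.epoch_profiles.items()}
        d["effect_sizes"] = {f"{a}:{b}": v
                             for (a, b), v in self.effect_sizes.items()}
        d["age_probs"] = {int(k): float(v) for k, v in self.age_probs.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "epoch_profiles" in d:
            d["epoch_profiles"] = {
                status: {ep: AutonomicProfile(**prof)
                         for ep, prof in eps.items()}
                for status, eps in d["epoch_profiles"].items()}
        if "age_probs" in d:
            d["age_probs"] = {int(k): float(v) for k, v in d["age_probs"].items()}
        return cls(**d)


def generate_rr_series(profile: AutonomicProfile, duration_s: float,
                       seed: int) -> RRSeries:
    """Generate an RR tachogram whose band powers hit the profile's targets.

    Each band gets one sinusoid at its geometric-centre frequency with
    amplitude sqrt(2 x power), so spectral analysis recovers the target
    power (A^2/2 per sinusoid).  Phases and the optional broadband term are
    drawn from ``seed``; the same seed reproduces the series bit for bit.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    amps = {band: np.sqrt(2.0 * getattr(profile, f"{band}_power"))
            for band in BAND_CENTRES}
    phases = {band: rng.uniform(0, 2 * np.pi) for band in BAND_CENTRES}
    noise_sd = np.sqrt(profile.noise_fraction * profile.band_total)

    beat_times, rr_values = [], []
    t = 0.0
    # guard against pathological profiles where modulation could exceed mean_rr
    floor = max(profile.mean_rr * 0.05, 1.0)
    while t < duration_s:
        rr = profile.mean_rr + profile.drift * (t / 60.0)
        for band, f0 in BAND_CENTRES.items():
            rr += amps[band] * np.sin(2 * np.pi * f0 * t + phases[band])
        if noise_sd > 0:
            rr += rng.normal(0.0, noise_sd)
        rr = max(rr, floor)
        t += rr / 1000.0
        beat_times.append(t)
        rr_values.append(rr)
    return RRSeries(beat_times=np.array(beat_times),
                    rr_ms=np.array(rr_values))


def _qrs_template(fs_hz: float) -> np.ndarray:
    """Stylised QRS complex: narrow R peak flanked by small Q and S dips."""
    t = np.arange(-0.06, 0.06, 1.0 / fs_hz)
    r = np.exp(-0.5 * (t / 0.008) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.025) / 0.010) ** 2)
    s = -0.20 * np.exp(-0.5 * ((t - 0.025) / 0.010) ** 2)
    return r + q + s


def generate_ecg(rr: RRSeries, fs_hz: float = 1024.0, seed: int = 0,
                 noise_sd: float = 0.0) -> ECGRecord:
    """Synthesise a single-lead ECG with QRS complexes at the RR beat times.

    The waveform is a unit-amplitude stylised QRS template placed at each
    beat time plus additive white noise of SD ``noise_sd`` (in units of the
    R-wave amplitude).  Morphology beyond a detectable QRS is not modelled.
    """
    if len(rr) == 0:
        raise InvalidParameterError("cannot synthesise ECG from an empty RR series")
    if fs_hz < 128:
        raise InvalidParameterError("fs_hz must be >= 128 for a resolvable QRS")
    rng = np.random.default_rng(seed)
    t_end = rr.beat_times[-1] + 0.3
    n = int(np.ceil(t_end * fs_hz))
    sig = np.zeros(n)
    template = _qrs_template(fs_hz)
    half = len(template) // 2
    for bt in rr.beat_times:
        centre = int(round(bt * fs_hz))
        lo = centre - half
        hi = lo + len(template)
        tlo = max(0, -lo)
        thi = len(template) - max(0, hi - n)
        sig[max(lo, 0):min(hi, n)] += template[tlo:thi]
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, n)
    return ECGRecord(samples=sig, fs_hz=fs_hz, start_time=0.0)


@dataclass
class SyntheticCohort:
    """A fully generated cohort: tables plus per-participant RR sessions."""

    config: CohortConfig
    participants: pd.DataFrame
    ssq: pd.DataFrame
    tlx: pd.DataFrame
    minicex: pd.DataFrame
    hrv_targets: pd.DataFrame
    rr_series: dict[str, RRSeries]

    def cohort_table(self, spectral: pd.DataFrame | None = None) -> pd.DataFrame:
        """One row per participant joining all instruments and HRV indices.

        ``spectral`` is a long participant x epoch table from the HRV stage;
        when omitted, the generator's target band powers stand in (useful for
        large cohorts generated without RR series).
        """
        out = self.participants.copy()
        out = out.merge(self.ssq[["participant", "ssq_total", "ss_category"]],
                        on="participant")
        out = out.merge(self.tlx, on="participant")
        mc = self.minicex[["participant", *MINICEX_ITEMS, "minicex_total",
                           "teacher_satisfaction", "learner_satisfaction"]]
        out = out.merge(mc, on="participant")
        if spectral is None:
            wide = self.hrv_targets.pivot(index="participant", columns="epoch",
                                          values=["vlf", "lf", "hf"])
        else:
            wide = spectral.pivot(index="participant", columns="epoch",
                                  values=["vlf", "lf", "hf", "tp", "lf_hf",
                                          "mean_rr"])
        wide.columns = [f"{band}_{ep}" for band, ep in wide.columns]
        out = out.merge(wide.reset_index(), on="participant")
        out["ss_positive"] = (out["ss_status"] == "ss_positive").astype(int)
        return out

    def temporal_profiles(self) -> dict[str, dict[float, int]]:
        minutes = sorted(MOTION_DEGREES_BY_MINUTE)
        return {
            row["participant"]: {float(m): int(row[f"severity_min{m}"])
                                 for m in minutes}
            for _, row in self.ssq.iterrows()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        self.ssq.to_csv(outdir / "ssq.csv", index=False)
        self.tlx.to_csv(outdir / "tlx.csv", index=False)
        self.minicex.to_csv(outdir / "minicex.csv", index=False)
        self.hrv_targets.to_csv(outdir / "hrv_targets.csv", index=False)
        self.config.to_yaml(outdir / "cohort_config.yaml")
        if self.rr_series:
            rrdir = outdir / "rr"
            rrdir.mkdir(exist_ok=True)
            for pid, rr in self.rr_series.items():
                rr.to_csv(rrdir / f"{pid}.csv")

    def serialize(self) -> str:
        """Canonical JSON serialisation for determinism checks."""
        payload = {
            "participants": self.participants.to_dict("records"),
            "ssq": self.ssq.to_dict("records"),
            "tlx": self.tlx.to_dict("records"),
            "minicex": self.minicex.to_dict("records"),
            "hrv_targets": self.hrv_targets.round(9).to_dict("records"),
            "rr": {pid: [float(f"{v:.9g}") for v in rr.rr_ms]
                   for pid, rr in sorted(self.rr_series.items())},
        }
        return json.dumps(payload, sort_keys=True)


def _symptom_ratings(total_points: int, rng: np.random.Generator) -> dict[str, int]:
    """Distribute a symptom-score sum over the 16 SSQ symptoms."""
    weights = np.array([SYMPTOM_WEIGHTS.get(s, 0.5) for s in SSQ_SYMPTOMS])
    ratings = {s: 0 for s in SSQ_SYMPTOMS}
    for _ in range(total_points):
        w = np.array([weights[i] if ratings[s] < 3 else 0.0
                      for i, s in enumerate(SSQ_SYMPTOMS)])
        pick = rng.choice(len(SSQ_SYMPTOMS), p=w / w.sum())
        ratings[SSQ_SYMPTOMS[pick]] += 1
    return ratings


def _ssq_sum_from_quantile(q: float) -> int:
    """Map a within-positive-group severity quantile to a symptom-score sum.

    Thresholds reproduce the observed marginal of positive totals: median
    sum 4 (total 14.96) with quartiles at sums 2 and 4 (7.48 and 14.96).
    """
    for cut, val in ((0.15, 1), (0.40, 2), (0.50, 3), (0.80, 4), (0.90, 5)):
        if q < cut:
            return val
    return 6


def _temporal_profile(max_rating: int) -> dict[int, int]:
    """Severity of the most representative symptom at the report minutes.

    Sickness begins around the 4th minute (before the fast-moving clips) and
    peaks at the 8th, mirroring the motion-degree timeline of the video.
    """
    shape = {0: 0.0, 2: 0.0, 4: 0.4, 6: 0.7, 8: 1.0, 10: 0.8}
    prof = {m: int(np.clip(round(max_rating * f), 0, 3)) for m, f in shape.items()}
    if max_rating >= 1 and prof[4] == 0:
        prof[4] = 1  # onset is at the 4th minute by construction
    return prof


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from a validated configuration."""
    n = config.n_participants
    R = config.latent_corr()
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(LATENTS)))
    root = np.random.SeedSequence(config.seed)
    substreams = root.spawn(n)

    # latent draws, one substream per participant
    Z = np.empty((n, len(LATENTS)))
    rngs = []
    for i, ss_ in enumerate(substreams):
        rng = np.random.default_rng(ss_)
        Z[i] = L @ rng.standard_normal(len(LATENTS))
        rngs.append(rng)
    lat = pd.DataFrame(Z, columns=LATENTS)

    # sickness status: the n_ss_positive most severe latent severities
    order = np.argsort(-lat["ss_severity"].to_numpy(), kind="stable")
    status = np.array(["ss_negative"] * n, dtype=object)
    status[order[:config.n_ss_positive]] = "ss_positive"
    p0 = 1.0 - config.n_ss_positive / n if n else 1.0

    pids = [f"P{i+1:03d}" for i in range(n)]
    part_rows, ssq_rows, tlx_rows, mc_rows, hrv_rows = [], [], [], [], []
    rr_series: dict[str, RRSeries] = {}

    minutes = sorted(MOTION_DEGREES_BY_MINUTE)
    for i, pid in enumerate(pids):
        rng = rngs[i]
        st = status[i]
        sev, vlf_l, pd_l, fr_l, pe_l = Z[i]

        age = int(rng.choice(sorted(config.age_probs),
                             p=[config.age_probs[k] for k in sorted(config.age_probs)]))
        sex = "F" if rng.uniform() < config.p_female else "M"
        part_rows.append({"participant": pid, "age": age, "sex": sex,
                          "ss_status": st})

        # --- SSQ -----------------------------------------------------------
        if st == "ss_positive":
            q = (ss.norm.cdf(sev) - p0) / max(1.0 - p0, 1e-12)
            total_points = _ssq_sum_from_quantile(float(np.clip(q, 0.0, 1.0)))
            ratings = _symptom_ratings(total_points, rng)
        else:
            ratings = {s: 0 for s in SSQ_SYMPTOMS}
        res = score_ssq(ratings)
        profile = _temporal_profile(max(ratings.values()))
        row = {"participant": pid, **ratings, "ssq_total": res.total,
               "ss_category": res.category}
        row.update({f"severity_min{m}": profile[m] for m in minutes})
        ssq_rows.append(row)

        # --- NASA-TLX ------------------------------------------------------
        pos = st == "ss_positive"
        tlx_vals = {
            "mental_demand": 13.0 + 3.7 * rng.standard_normal(),
            "physical_demand": (13.8 + 3.0 * pd_l) if pos else (8.8 + 4.6 * pd_l),
            "temporal_demand": 10.0 + 3.0 * rng.standard_normal(),
            "performance": 10.0 + 7.4 * rng.standard_normal(),
            "effort": 12.5 + 3.0 * rng.standard_normal(),
            "frustration": (12.3 + 4.9 * fr_l) if pos else (5.7 + 4.4 * fr_l),
        }
        tlx_rows.append({"participant": pid,
                         **{k: float(np.clip(round(v, 1), 0.0, 20.0))
                            for k, v in tlx_vals.items()}})

        # --- Mini-CEX ------------------------------------------------------
        counsel_l = -0.48 * fr_l + np.sqrt(1 - 0.48 ** 2) * rng.standard_normal()
        bases = {
            "medical_interview": 5.6 + 0.8 * rng.standard_normal(),
            "physical_examination": (4.7 if pos else 5.7) + 0.8 * pe_l,
            "professionalism": 6.1 + 0.8 * rng.standard_normal(),
            "clinical_judgment": 5.8 + 0.8 * rng.standard_normal(),
            "counseling_skills": (5.3 if pos else 6.1) + 0.8 * counsel_l,
            "organization_efficiency": 5.8 + 0.8 * rng.standard_normal(),
            "overall_competence": (5.4 if pos else 5.8) + 0.8 * pe_l
                                   + 0.3 * rng.standard_normal(),
        }
        items = {k: int(np.clip(round(v), 1, 9)) for k, v in bases.items()}
        mc_rows.append({
            "participant": pid, **items,
            "minicex_total": int(sum(items.values())),
            "teacher_satisfaction": int(np.clip(round((8.3 if pos else 8.8)
                                        + 0.5 * rng.standard_normal()), 1, 9)),
            "learner_satisfaction": int(np.clip(round(8.9
                                        + 0.4 * rng.standard_normal()), 1, 9)),
        })

        # --- HRV targets and RR sessions ----------------------------------
        seg_parts = []
        for ep in EPOCH_LABELS:
            base = config.epoch_profiles[st][ep]
            if ep == "t6_10":
                lam = config.vlf_latent_share
                mix = lam * vlf_l + np.sqrt(1 - lam ** 2) * rng.standard_normal()
                vlf = base.vlf_power * float(np.exp(config.vlf_sigma * mix))
            else:
                vlf = base.vlf_power * float(np.exp(
                    config.band_sigma * rng.standard_normal()))
            lf = base.lf_power * float(np.exp(config.band_sigma * rng.standard_normal()))
            hf = base.hf_power * float(np.exp(config.band_sigma * rng.standard_normal()))
            mean_rr = base.mean_rr + 40.0 * rng.standard_normal()
            prof = AutonomicProfile(mean_rr=mean_rr, vlf_power=vlf, lf_power=lf,
                                    hf_power=hf, drift=base.drift,
                                    noise_fraction=base.noise_fraction)
            hrv_rows.append({"participant": pid, "epoch": ep,
                             "mean_rr": mean_rr, "vlf": vlf, "lf": lf, "hf": hf})
            if config.generate_rr:
                epoch_seed = int(rng.integers(0, 2 ** 31 - 1))
                seg = generate_rr_series(prof, 300.0, seed=epoch_seed)
                start = EPOCH_WINDOWS[ep][0]
                mask = seg.beat_times + start < EPOCH_WINDOWS[ep][1]
                seg_parts.append((seg.beat_times[mask] + start, seg.rr_ms[mask]))
        if config.generate_rr:
            times = np.concatenate([p[0] for p in seg_parts])
            vals = np.concatenate([p[1] for p in seg_parts])
            keep = np.concatenate([[True], np.diff(times) > 0])
            rr_series[pid] = RRSeries(beat_times=times[keep], rr_ms=vals[keep])

    return SyntheticCohort(
        config=config,
        participants=pd.DataFrame(part_rows),
        ssq=pd.DataFrame(ssq_rows),
        tlx=pd.DataFrame(tlx_rows),
        minicex=pd.DataFrame(mc_rows),
        hrv_targets=pd.DataFrame(hrv_rows),
        rr_series=rr_series,
    )
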