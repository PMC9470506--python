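"""Scoring and validation of the study questionnaires.

Three instruments are covered:

* **SSQ** — the 16-item Simulator Sickness Questionnaire.  Each symptom is
  rated 0 (none) to 3 (severe); the total score is the plain sum of the 16
  ratings multiplied by 3.74.  A total of 0 is "none", totals in (0, 20] are
  "mild" and totals above 20 are "significant" simulator sickness.  Subscale
  *membership* (nausea / oculomotor / disorientation) uses the standard
  Kennedy symptom-to-subscale mapping; the subscale weighted scores are
  deliberately not computed because the total here uses the simplified
  x3.74 rule only.
* **NASA-TLX** — six workload subscales, each a 0-20 visual-analogue value.
  No pairwise weighting is applied; the six raw subscales are analysed
  directly.
* **Mini-CEX** — seven clinical competencies each rated 1-9 (total 7-63)
  plus teacher and learner satisfaction on the same nine-point scale.

A three-point per-timestamp motion-degree profile of the learning video
(0 sitting still, 1 slightly fast-moving, 2 moderately fast-moving) supports
the motion-vs-sickness temporal association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as ss

from .errors import ValidationError

SSQ_WEIGHT = 3.74
MILD_SS_CUTOFF = 20.0

SSQ_SYMPTOMS = (
    "general_discomfort",
    "fatigue",
    "headache",
    "eye_strain",
    "difficulty_focusing",
    "increased_salivation",
    "sweating",
    "nausea",
    "difficulty_concentrating",
    "fullness_of_head",
    "blurred_vision",
    "dizzy_eyes_open",
    "dizzy_eyes_closed",
    "vertigo",
    "stomach_awareness",
    "burping",
)

# Kennedy et al. symptom-to-subscale membership (N / O / D).
SSQ_SUBSCALES = {
    "nausea": (
        "general_discomfort", "increased_salivation", "sweating", "nausea",
        "difficulty_concentrating", "stomach_awareness", "burping",
    ),
    "oculomotor": (
        "general_discomfort", "fatigue", "headache", "eye_strain",
        "difficulty_focusing", "difficulty_concentrating", "blurred_vision",
    ),
    "disorientation": (
        "difficulty_focusing", "nausea", "fullness_of_head", "blurred_vision",
        "dizzy_eyes_open", "dizzy_eyes_closed", "vertigo",
    ),
}

TLX_SUBSCALES = (
    "mental_demand", "physical_demand", "temporal_demand",
    "performance", "effort", "frustration",
)

MINICEX_ITEMS = (
    "medical_interview", "physical_examination", "professionalism",
    "clinical_judgment", "counseling_skills", "organization_efficiency",
    "overall_competence",
)


@dataclass
class SSQResult:
    ratings: dict[str, int]
    total: float
    subscale_flags: dict[str, bool]
    category: str
    temporal_profile: dict[int, int] | None = None


@dataclass
class TLXResult:
    mental_demand: float
    physical_demand: float
    temporal_demand: float
    performance: float
    effort: float
    frustration: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in TLX_SUBSCALES}


@dataclass
class MiniCEXResult:
    items: dict[str, int]
    total: int
    teacher_satisfaction: int
    learner_satisfaction: int


@dataclass
class MotionProfile:
    """Per-timestamp motion degree of the learning video (0/1/2 scale)."""

    degrees: dict[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, d in self.degrees.items():
            if d not in (0, 1, 2):
                raise ValidationError(
                    f"motion degree at t={t} is {d}; must be 0, 1 or 2")

    @property
    def total_degree(self) -> int:
        return int(sum(self.degrees.values()))

    def at(self, t: float) -> int:
        return self.degrees[t]


def score_ssq(ratings, temporal_profile: dict[int, int] | None = None) -> SSQResult:
    """Score one SSQ response: total = (sum of 16 ratings) x 3.74.

    ``ratings`` may be a mapping keyed by symptom name or a sequence of 16
    values in symptom order.  Each rating must be an integer 0-3.
    """
    if isinstance(ratings, dict):
        unknown = set(ratings) - set(SSQ_SYMPTOMS)
        if unknown:
            raise ValidationError(f"unknown SSQ symptoms: {sorted(unknown)}")
        missing = set(SSQ_SYMPTOMS) - set(ratings)
        if missing:
            raise ValidationError(f"missing SSQ symptoms: {sorted(missing)}")
        rmap = {k: ratings[k] for k in SSQ_SYMPTOMS}
    else:
        seq = list(ratings)
        if len(seq) != 16:
            raise ValidationError(f"SSQ needs exactly 16 ratings, got {len(seq)}")
        rmap = dict(zip(SSQ_SYMPTOMS, seq))
    for name, v in rmap.items():
        if not (isinstance(v, (int, np.integer)) or float(v).is_integer()) \
                or not 0 <= int(v) <= 3:
            raise ValidationError(f"rating for {name!r} is {v!r}; must be 0-3")
    rmap = {k: int(v) for k, v in rmap.items()}
    total = sum(rmap.values()) * SSQ_WEIGHT
    flags = {sub: any(rmap[s] > 0 for s in members)
             for sub, members in SSQ_SUBSCALES.items()}
    if temporal_profile is not None:
        for minute, sev in temporal_profile.items():
            if sev not in (0, 1, 2, 3):
                raise ValidationError(
                    f"temporal severity at minute {minute} is {sev}; must be 0-3")
    return SSQResult(ratings=rmap, total=total, subscale_flags=flags,
                     category=classify_ss(total), temporal_profile=temporal_profile)


def classify_ss(total: float) -> str:
    """Categorise a total SSQ score: 0 none, (0, 20] mild, > 20 significant."""
    if total < 0:
        raise ValidationError(f"total SSQ score cannot be negative ({total})")
    if total == 0:
        return "none"
    if total <= MILD_SS_CUTOFF:
        return "mild"
    return "significant"


def validate_tlx(raw) -> TLXResult:
    """Validate six NASA-TLX subscale values (each within [0, 20]).

    Values are passed through unmodified — nothing is clamped; out-of-range
    input raises naming the offending subscale.
    """
    if isinstance(raw, dict):
        unknown = set(raw) - set(TLX_SUBSCALES)
        if unknown:
            raise ValidationError(f"unknown TLX subscales: {sorted(unknown)}")
        missing = set(TLX_SUBSCALES) - set(raw)
        if missing:
            raise ValidationError(f"missing TLX subscales: {sorted(missing)}")
        vals = [raw[k] for k in TLX_SUBSCALES]
    else:
        vals = list(raw)
        if len(vals) != 6:
            raise ValidationError(f"TLX needs exactly 6 subscales, got {len(vals)}")
    for name, v in zip(TLX_SUBSCALES, vals):
        v = float(v)
        if not np.isfinite(v) or not 0.0 <= v <= 20.0:
            raise ValidationError(f"TLX subscale {name!r} is {v}; must be in [0, 20]")
    return TLXResult(*(float(v) for v in vals))


def score_minicex(items, satisfaction) -> MiniCEXResult:
    """Score a Mini-CEX form: total = sum of the seven 1-9 item ratings."""
    if isinstance(items, dict):
        unknown = set(items) - set(MINICEX_ITEMS)
        if unknown:
            raise ValidationError(f"unknown Mini-CEX items: {sorted(unknown)}")
        missing = set(MINICEX_ITEMS) - set(items)
        if missing:
            raise ValidationError(f"missing Mini-CEX items: {sorted(missing)}")
        vals = [items[k] for k in MINICEX_ITEMS]
    else:
        vals = list(items)
        if len(vals) != 7:
            raise ValidationError(f"Mini-CEX needs exactly 7 items, got {len(vals)}")
    imap = {}
    for name, v in zip(MINICEX_ITEMS, vals):
        if not float(v).is_integer() or not 1 <= int(v) <= 9:
            raise ValidationError(f"Mini-CEX item {name!r} is {v!r}; must be 1-9")
        imap[name] = int(v)
    sat = list(satisfaction)
    if len(sat) != 2:
        raise ValidationError("satisfaction needs (teacher, learner) values")
    for who, v in zip(("teacher", "learner"), sat):
        if not float(v).is_integer() or not 1 <= int(v) <= 9:
            raise ValidationError(f"{who} satisfaction is {v!r}; must be 1-9")
    return MiniCEXResult(items=imap, total=sum(imap.values()),
                         teacher_satisfaction=int(sat[0]),
                         learner_satisfaction=int(sat[1]))


def motion_ssq_association(motion: MotionProfile,
                           ssq_profiles: dict[str, dict[float, int]]) -> dict:
    """Spearman correlation of motion degree with temporal SS severity.

    Pools (degree, severity) pairs across participants and timepoints at the
    timestamps shared by the motion profile and every severity profile.
    Returns a dict with r, two-sided p, n, and a ``degenerate`` flag when
    either pooled variable has zero variance (e.g. an entirely SS-negative
    cohort).
    """
    degrees, severities = [], []
    for pid, profile in ssq_profiles.items():
        for t, sev in profile.items():
            if t in motion.degrees:
                degrees.append(motion.degrees[t])
                severities.append(sev)
    n = len(degrees)
    if n < 3:
        raise ValidationError("need at least 3 aligned (motion, severity) pairs")
    degrees = np.asarray(degrees, dtype=float)
    severities = np.asarray(severities, dtype=float)
    if np.ptp(degrees) == 0 or np.ptp(severities) == 0:
        return {"r": None, "p": None, "n": n, "degenerate": True}
    r, p = ss.spearmanr(degrees, severities)
    return {"r": float(r), "p": float(p), "n": n, "degenerate": False}
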