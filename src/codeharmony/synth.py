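"""Paired-site synthetic EHR generator with known coding-channel differences.

Two sites share the same latent clinical event processes — per-patient
Poisson episode streams for a set of conditions, with log-linear covariate
effects on the episode rates — but differ only in how episodes are coded.
Each site has an emission channel per condition: an episode emits the
patient's substitutable "style" code (see :class:`ChannelEntry`) with the
channel's pooled style probability, plus each episode-level entry (e.g. an
accompanying procedure marker) independently with its own probability; all
endorsements are dated within the co-emission window of the episode date,
as a clinical encounter generates several codes together.  Coding-channel
differences are therefore the *only* systematic cross-site differences,
which gives every downstream stage a known ground truth:

* substitution: a condition emits code X at site A but code Y at site B,
  at equal intensity, so group totals match while members diverge;
* granularity: site A splits a condition over several specific codes where
  site B uses one unspecified code;
* imbalanced sharing: both sites use the same pair of codes with swapped
  preferences (the pattern behind published specific-vs-unspecified
  cataract coding differences);
* local codes: entries present in only one site's channels;
* frequency inflation: a per-entry multiplier that repeats endorsements of
  an emitted code within the co-emission window.

Because episodes, not raw code draws, drive emission, codes of the same
condition share their co-occurrence geometry across sites — the premise
that makes embedding alignment meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .store import CovariateTable, EventTable, GroupCatalog

START_DATE = pd.Timestamp("2018-01-01")

SITES = ("A", "B")


@dataclass(frozen=True)
class ChannelEntry:
    """One way a site codes a condition's episodes.

    ``style=True`` marks substitutable codes chosen once per patient (a
    provider "coding style"): the patient's episodes always emit that
    patient's style code, so sibling style codes are mutually exclusive
    within a patient, as with provider-driven code substitution.
    ``style=False`` entries (e.g. accompanying procedure markers) are drawn
    per episode.
    """

    code: str
    prob: float
    mult: float = 1.0  # mean endorsements per emission (frequency inflation)
    style: bool = False


@dataclass(frozen=True)
class Condition:
    cond_id: str
    base_rate: float  # episodes per person-year at covariate means
    coefs: dict = field(default_factory=dict)  # log-rate coefs on standardized covariates


@dataclass
class SynthConfig:
    """Complete description of a paired-site generating process."""

    conditions: list[Condition]
    channels: dict[str, dict[str, list[ChannelEntry]]]  # site -> cond_id -> entries
    groups: dict[str, list[str]]  # group_id -> member codes
    n_patients: int = 1000
    study_years: float = 4.0
    age_mean: float = 63.0
    age_sd: float = 10.0
    sex_p: float = 0.49
    insulin_p: float = 0.21
    elix_mean: float = 3.5
    local_codes: dict[str, list[str]] = field(default_factory=dict)  # site -> codes
    code_types: dict[str, str] = field(default_factory=dict)
    window_days: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for cond in self.conditions:
            if cond.base_rate <= 0:
                raise ValueError(f"nonpositive rate for condition {cond.cond_id}")
        for site, chans in self.channels.items():
            for cid, entries in chans.items():
                total = sum(e.prob for e in entries)
                if any(not (0 <= e.prob <= 1) for e in entries) or total > 1 + 1e-9:
                    raise ValueError(
                        f"emission probabilities for condition {cid} at site {site} "
                        f"must be in [0,1] and sum to <=1 (got {total:.3f})"
                    )
                if any(e.mult < 1 for e in entries):
                    raise ValueError("frequency multiplier must be >= 1")

    def site_vocab(self, site: str) -> list[str]:
        codes = {e.code for entries in self.channels[site].values() for e in entries}
        return sorted(codes)

    def code_type(self, code: str) -> str:
        if code in self.code_types:
            return self.code_types[code]
        for site, codes in self.local_codes.items():
            if code in codes:
                return "LOCAL"
        return "ICD10"

    def group_catalog(self) -> GroupCatalog:
        mapping = {c: g for g, codes in self.groups.items() for c in codes}
        return GroupCatalog(code_to_group=mapping)


@dataclass
class GroundTruth:
    """Condition-level cross-site correspondence.

    A source (site A) code's true targets are the site-B codes emitted by
    the same condition(s) within the same clinical group, weighted by the
    B-channel emission intensities.  The correspondence is defined at
    condition resolution because substitutable sibling codes of one
    condition are statistically exchangeable views of the same episodes
    (distinguishable only by frequency), so mapping onto any sibling of
    the right condition is correct.
    """

    mapping: dict[str, list[tuple[str, float]]]
    null_groups: list[str]
    planted_groups: list[str]

    def support(self, source_code: str) -> set[str]:
        return {ref for ref, _ in self.mapping.get(source_code, [])}

    def to_json(self) -> str:
        return json.dumps(
            {
                "mapping": {k: [[r, w] for r, w in v] for k, v in self.mapping.items()},
                "null_groups": self.null_groups,
                "planted_groups": self.planted_groups,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# ground truth and analytic expectations (no simulation)
# ---------------------------------------------------------------------------


def _channel_signature(entries: list[ChannelEntry]) -> tuple:
    return tuple(
        sorted((e.code, round(e.prob, 12), round(e.mult, 12), e.style) for e in entries)
    )


def derive_ground_truth(config: SynthConfig) -> GroundTruth:
    catalog = config.group_catalog()
    # a group is null iff its restriction of every channel is identical
    # across sites (then its member counts are identically distributed)
    def group_signature(site: str, g: str) -> tuple:
        return tuple(
            sorted(
                (cid, e.code, round(e.prob, 12), round(e.mult, 12))
                for cid, entries in config.channels[site].items()
                for e in entries
                if catalog.group_of(e.code) == g
            )
        )

    null_groups = sorted(
        g for g in catalog.groups if group_signature("A", g) == group_signature("B", g)
    )
    planted_groups = sorted(set(catalog.groups) - set(null_groups))

    mapping: dict[str, list[tuple[str, float]]] = {}
    b_by_cond = config.channels["B"]
    for code in config.site_vocab("A"):
        conds = [
            cid
            for cid, entries in config.channels["A"].items()
            if any(e.code == code for e in entries)
        ]
        g = catalog.group_of(code)
        weights: dict[str, float] = {}
        for cid in conds:
            for e in b_by_cond.get(cid, []):
                if catalog.group_of(e.code) == g:
                    weights[e.code] = weights.get(e.code, 0.0) + e.prob * e.mult
        total = sum(weights.values())
        if total > 0:
            mapping[code] = sorted((r, w / total) for r, w in weights.items())
    return GroundTruth(mapping=mapping, null_groups=null_groups, planted_groups=planted_groups)


def _mean_rate_multiplier(config: SynthConfig, coefs: dict) -> float:
    """E[exp(linear predictor)] over the covariate distribution (closed
    form: the covariates are independent with known moment generating
    functions; age and elixhauser enter standardized, sex/insulin centered)."""
    out = 1.0
    if "age" in coefs:
        b = coefs["age"]
        out *= np.exp(b**2 / 2)  # standard normal MGF
    for name, p in (("sex", config.sex_p), ("insulin", config.insulin_p)):
        if name in coefs:
            b = coefs[name]
            out *= (1 - p) * np.exp(-b * p) + p * np.exp(b * (1 - p))
    if "elixhauser" in coefs:
        b = coefs["elixhauser"]
        lam = config.elix_mean
        s = np.sqrt(lam)
        out *= np.exp(lam * (np.exp(b / s) - 1)) * np.exp(-b * lam / s)
    return float(out)


def expected_code_rates(config: SynthConfig, site: str) -> dict[str, float]:
    """Expected endorsements per person-year for every code at a site,
    computed analytically from the emission tables (no simulation)."""
    rates: dict[str, float] = {}
    cond_by_id = {c.cond_id: c for c in config.conditions}
    for cid, entries in config.channels[site].items():
        cond = cond_by_id[cid]
        lam = cond.base_rate * _mean_rate_multiplier(config, cond.coefs)
        for e in entries:
            rates[e.code] = rates.get(e.code, 0.0) + lam * e.prob * e.mult
    return rates


def expected_person_time(config: SynthConfig) -> float:
    """Mean follow-up per patient: person-time is uniform on
    (study_years/8, study_years]."""
    lo = config.study_years / 8
    return (lo + config.study_years) / 2


def expected_smoothed_ratio(
    config: SynthConfig, codes: list[str], kappa: int = 10
) -> float:
    """Expected smoothed frequency ratio for a code or group of codes,
    from the analytic per-code rates."""
    pt = config.n_patients * expected_person_time(config)
    ra = expected_code_rates(config, "A")
    rb = expected_code_rates(config, "B")
    f_a = sum(ra.get(c, 0.0) for c in codes) * pt
    f_b = sum(rb.get(c, 0.0) for c in codes) * pt
    return ((f_a + kappa) / pt) / ((f_b + kappa) / pt)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_covariates(config: SynthConfig, rng: np.random.Generator, site: str):
    n = config.n_patients
    ids = [f"{site}{i:05d}" for i in range(n)]
    age = rng.normal(config.age_mean, config.age_sd, n)
    sex = (rng.random(n) < config.sex_p).astype(float)
    insulin = (rng.random(n) < config.insulin_p).astype(float)
    elix = rng.poisson(config.elix_mean, n).astype(float)
    pt = rng.uniform(config.study_years / 8, config.study_years, n)
    frame = pd.DataFrame(
        {
            "person_time": pt,
            "age": age,
            "sex": sex,
            "insulin_use": insulin,
            "elixhauser": elix,
        },
        index=pd.Index(ids, name="patient_id"),
    )
    return CovariateTable(frame=frame)


def _linear_predictor(config: SynthConfig, cov: CovariateTable, coefs: dict) -> np.ndarray:
    f = cov.frame
    lp = np.zeros(len(f))
    if "age" in coefs:
        lp += coefs["age"] * (f["age"].to_numpy() - config.age_mean) / config.age_sd
    if "sex" in coefs:
        lp += coefs["sex"] * (f["sex"].to_numpy() - config.sex_p)
    if "insulin" in coefs:
        lp += coefs["insulin"] * (f["insulin_use"].to_numpy() - config.insulin_p)
    if "elixhauser" in coefs:
        lp += (
            coefs["elixhauser"]
            * (f["elixhauser"].to_numpy() - config.elix_mean)
            / np.sqrt(config.elix_mean)
        )
    return lp


def _generate_site(
    config: SynthConfig, rng: np.random.Generator, site: str
) -> tuple[EventTable, CovariateTable]:
    cov = _draw_covariates(config, rng, site)
    pt_days = np.maximum((cov.person_time.to_numpy() * 365.25).astype(int), 1)
    patient_ids = np.asarray(cov.patients)
    all_pid: list[np.ndarray] = []
    all_day: list[np.ndarray] = []
    all_code: list[np.ndarray] = []
    for cond in config.conditions:
        entries = config.channels[site].get(cond.cond_id, [])
        if not entries:
            continue
        lam = cond.base_rate * np.exp(_linear_predictor(config, cov, cond.coefs))
        n_ep = rng.poisson(lam * cov.person_time.to_numpy())
        total = int(n_ep.sum())
        style_entries = [e for e in entries if e.style]
        indep_entries = [e for e in entries if not e.style]
        p_style = sum(e.prob for e in style_entries)
        if style_entries:
            # per-patient coding style, proportional to the entry weights
            sp = np.array([e.prob for e in style_entries]) / p_style
            style_of = rng.choice(len(style_entries), size=len(patient_ids), p=sp)
        if total == 0:
            continue
        owner = np.repeat(np.arange(len(patient_ids)), n_ep)
        ep_day = rng.integers(0, pt_days[owner])
        # an episode can emit several codes, all dated within the
        # co-emission window of the episode date: the patient's style code
        # (with the pooled style probability) plus each independent entry
        # with its own probability
        resolved = [*style_entries, *indep_entries]
        emissions: list[tuple[np.ndarray, int]] = []  # (episode rows, entry idx)
        if style_entries:
            hit = np.flatnonzero(rng.random(total) < p_style)
            ep_entry = style_of[owner[hit]]
            for k in range(len(style_entries)):
                sel = hit[ep_entry == k]
                if sel.size:
                    emissions.append((sel, k))
        for j, e in enumerate(indep_entries):
            sel = np.flatnonzero(rng.random(total) < e.prob)
            if sel.size:
                emissions.append((sel, len(style_entries) + j))
        for sel, k in emissions:
            entry = resolved[k]
            reps = 1 + rng.poisson(max(entry.mult - 1.0, 0.0), size=sel.size)
            own = np.repeat(owner[sel], reps)
            base_day = np.repeat(ep_day[sel], reps)
            offset = rng.integers(0, config.window_days + 1, size=len(own))
            all_pid.append(patient_ids[own])
            all_day.append(base_day + offset)
            all_code.append(np.full(len(own), entry.code, dtype=object))
    if all_pid:
        pid = np.concatenate(all_pid)
        day = np.concatenate(all_day)
        code = np.concatenate(all_code)
    else:
        pid = np.array([], dtype=object)
        day = np.array([], dtype=int)
        code = np.array([], dtype=object)
    frame = pd.DataFrame(
        {
            "patient_id": pid,
            "date": START_DATE + pd.to_timedelta(day, unit="D"),
            "code": code,
        }
    )
    frame["code_type"] = frame["code"].map(config.code_type).astype(object)
    frame = frame.sort_values(["patient_id", "date", "code"], kind="stable").reset_index(drop=True)
    return EventTable(site_id=site, frame=frame), cov


def generate_cohort(
    config: SynthConfig, seed: int | None = None
) -> tuple[EventTable, CovariateTable, EventTable, CovariateTable, GroundTruth]:
    """Draw both sites' cohorts from the shared latent process.

    Reproducible: all randomness flows through one generator seeded by
    ``seed`` (or ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    events_a, cov_a = _generate_site(config, rng, "A")
    events_b, cov_b = _generate_site(config, rng, "B")
    return events_a, cov_a, events_b, cov_b, derive_ground_truth(config)


# ---------------------------------------------------------------------------
# scenario presets — these ARE the study conditions for the test harness
# ---------------------------------------------------------------------------


def _null_conditions(prefix: str = "n", n_groups: int = 10, codes_per_group: int = 3):
    """Conditions coded identically at both sites, one clinical group each."""
    rates = [0.6, 0.9, 1.2, 1.5, 1.8, 2.1, 2.4, 2.7, 3.0, 1.0]
    coef_cycle = [
        {"age": 0.3},
        {"sex": 0.4},
        {"insulin": 0.4},
        {"elixhauser": 0.3},
        {"age": -0.3},
        {"sex": -0.4, "age": 0.2},
        {"insulin": -0.4},
        {"elixhauser": -0.3},
        {"age": 0.2, "sex": 0.3},
        {"insulin": 0.3, "elixhauser": 0.2},
    ]
    probs = [0.45, 0.30, 0.15][:codes_per_group]
    conditions, channel, groups = [], {}, {}
    for k in range(n_groups):
        cid = f"{prefix}{k + 1}"
        conditions.append(
            Condition(cond_id=cid, base_rate=rates[k % len(rates)], coefs=coef_cycle[k % len(coef_cycle)])
        )
        codes = [f"N{k + 1}_{j + 1}" for j in range(codes_per_group)]
        channel[cid] = [ChannelEntry(c, p, style=True) for c, p in zip(codes, probs)]
        groups[f"grp_n{k + 1}"] = codes
    return conditions, channel, groups


def scenario_null(n_patients: int = 1000, seed: int = 0) -> SynthConfig:
    """Identical coding channels at both sites: the type-I-error harness.
    Ground truth is the identity on the shared vocabulary."""
    conditions, channel, groups = _null_conditions()
    return SynthConfig(
        conditions=conditions,
        channels={"A": dict(channel), "B": dict(channel)},
        groups=groups,
        n_patients=n_patients,
        seed=seed,
    )


def scenario_substitution(n_patients: int = 1000, seed: int = 0) -> SynthConfig:
    """One planted group with code substitution at equal group intensity.

    The planted group mixes two substitution flavors observed in practice:
    two conditions coded with site-exclusive sibling codes (pure
    substitution), and two conditions sharing a specific/unspecified code
    pair with swapped preferences across sites.  Each planted condition
    also emits a shared marker code (a separate group) so that embeddings
    can anchor the conditions across sites.  Five null groups and two
    site-B-only local codes complete the scene.
    """
    conditions, channel_shared, groups = _null_conditions(n_groups=5, codes_per_group=2)
    chan_a: dict[str, list[ChannelEntry]] = dict(channel_shared)
    chan_b: dict[str, list[ChannelEntry]] = dict(channel_shared)

    planted = [
        # (condition, rate, coefs, A entries, B entries)
        ("c1", 3.0, {"sex": 1.4},
         [ChannelEntry("SUB_A1", 0.50, style=True), ChannelEntry("MRK1", 0.40)],
         [ChannelEntry("SUB_B1", 0.50, style=True), ChannelEntry("MRK1", 0.40)]),
        ("c2", 3.0, {"insulin": 1.4},
         [ChannelEntry("SUB_A2", 0.50, style=True), ChannelEntry("MRK2", 0.40)],
         [ChannelEntry("SUB_B2", 0.50, style=True), ChannelEntry("MRK2", 0.40)]),
        ("c3", 2.6, {"age": 0.9},
         [ChannelEntry("SPC3", 0.45, style=True), ChannelEntry("UNS3", 0.10, style=True),
          ChannelEntry("MRK3", 0.35)],
         [ChannelEntry("SPC3", 0.10, style=True), ChannelEntry("UNS3", 0.45, style=True),
          ChannelEntry("MRK3", 0.35)]),
        ("c4", 2.6, {"elixhauser": 0.9},
         [ChannelEntry("SPC4", 0.45, style=True), ChannelEntry("UNS4", 0.10, style=True),
          ChannelEntry("MRK4", 0.35)],
         [ChannelEntry("SPC4", 0.10, style=True), ChannelEntry("UNS4", 0.45, style=True),
          ChannelEntry("MRK4", 0.35)]),
    ]
    for cid, rate, coefs, ea, eb in planted:
        conditions.append(Condition(cond_id=cid, base_rate=rate, coefs=coefs))
        chan_a[cid] = ea
        chan_b[cid] = eb
    # site-B-only local codes
    conditions.append(Condition(cond_id="loc", base_rate=1.5))
    chan_a["loc"] = []
    chan_b["loc"] = [ChannelEntry("LOCB1", 0.30), ChannelEntry("LOCB2", 0.30)]

    groups["grp_sub"] = ["SPC3", "SPC4", "SUB_A1", "SUB_A2", "SUB_B1", "SUB_B2", "UNS3", "UNS4"]
    groups["grp_mrk"] = ["MRK1", "MRK2", "MRK3", "MRK4"]
    return SynthConfig(
        conditions=conditions,
        channels={"A": chan_a, "B": chan_b},
        groups=groups,
        n_patients=n_patients,
        local_codes={"B": ["LOCB1", "LOCB2"]},
        code_types={"MRK1": "CPT", "MRK2": "CPT", "MRK3": "CPT", "MRK4": "CPT"},
        seed=seed,
    )


def scenario_granularity(n_patients: int = 1000, seed: int = 0) -> SynthConfig:
    """Site A splits one condition over three laterality codes where site B
    emits a single unspecified code with equal total intensity."""
    conditions, channel_shared, groups = _null_conditions(n_groups=5, codes_per_group=2)
    chan_a: dict[str, list[ChannelEntry]] = dict(channel_shared)
    chan_b: dict[str, list[ChannelEntry]] = dict(channel_shared)
    conditions.append(Condition(cond_id="cat", base_rate=2.4, coefs={"age": 0.8}))
    chan_a["cat"] = [
        ChannelEntry("LAT_R", 0.15, style=True),
        ChannelEntry("LAT_L", 0.15, style=True),
        ChannelEntry("LAT_B", 0.15, style=True),
        ChannelEntry("MRKC", 0.30),
    ]
    chan_b["cat"] = [ChannelEntry("UNSP", 0.45, style=True), ChannelEntry("MRKC", 0.30)]
    groups["grp_cat"] = ["LAT_B", "LAT_L", "LAT_R", "UNSP"]
    groups["grp_mrk"] = ["MRKC"]
    return SynthConfig(
        conditions=conditions,
        channels={"A": chan_a, "B": chan_b},
        groups=groups,
        n_patients=n_patients,
        seed=seed,
    )


SCENARIOS = {
    "null": scenario_null,
    "substitution": scenario_substitution,
    "granularity": scenario_granularity,
}


def with_patients(config: SynthConfig, n_patients: int) -> SynthConfig:
    """Same generating process at a different cohort size."""
    return replace(config, n_patients=n_patients)
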