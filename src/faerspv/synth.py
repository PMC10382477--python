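"""Synthetic FAERS-like corpus generator with exact ground truth.

Real spontaneous-report archives are large and carry no ground truth,
so every pipeline stage here is exercised against simulated quarterly
bundles whose generative bookkeeping is exact: the generator records
which cases are sole-primary-suspect for each target drug, which carry
each event, which are statin-coexposed, which are duplicate re-emissions
and which are deliberate multi-suspect exclusions — so screening output
can be compared set-for-set against the truth.

Generative model, per case:

* one primary-suspect (PS) drug drawn from the catalogue (six SSRIs
  with FAERS-plausible marginal exposure probabilities) or from a
  background pool covering the remaining mass;
* each event term *e* occurs with probability min(1, p_e * lambda(d, e)),
  where the signal multiplier lambda is the drug-event relative
  reporting-rate ratio (1 everywhere under the null); a filler term
  guarantees REAC is never empty;
* therapy start precedes the FDA receipt date; the event date is the
  therapy start plus a log-normal onset in days (rounded), giving the
  heavy right tail typical of time-to-onset histograms; a small
  error rate flips the event date before the start to exercise the
  negative-duration exclusion, and partial/missing date rates exercise
  the inaccurate-date exclusion;
* with probability ``dup_rate`` the case is re-emitted under the same
  CASEID with a new PRIMARYID and a strictly later FDA_DT; a separate
  small ``dup_same_day_rate`` emits a same-FDA_DT duplicate so the
  highest-PRIMARYID tie-break is exercised;
* with probability ``multi_ps_rate`` a second catalogue drug is added
  in the PS role (ground-truth "excluded" cases);
* with probability ``comed_rate`` a statin concomitant row is added.

PRIMARYID is CASEID*100 + version, so versions of a case sort
adjacently and the surviving version is always CASEID*100 + the highest
version. Generation is a pure function of the config: the same seed
yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .faers_io import Corpus, RawQuarterBundle, TABLE_NAMES, combine_bundles

__all__ = [
    "DrugSpec",
    "SynthConfig",
    "GroundTruth",
    "simulate",
    "generate",
    "write_corpus",
    "corpus_from_tables",
    "Margins",
    "published_margins",
]


@dataclass(frozen=True)
class DrugSpec:
    """One catalogue drug: canonical name, emission variants, exposure prob."""

    canonical: str
    verbatims: tuple[str, ...]
    probability: float


_DEFAULT_DRUGS = (
    DrugSpec("sertraline", ("SERTRALINE", "SERTRALINE HCL 50MG", "ZOLOFT"), 0.030),
    DrugSpec("fluoxetine", ("FLUOXETINE", "FLUOXETINE HYDROCHLORIDE", "PROZAC 20MG"), 0.017),
    DrugSpec("paroxetine", ("PAROXETINE", "PAXIL", "SEROXAT 20 MG"), 0.015),
    DrugSpec("escitalopram", ("ESCITALOPRAM", "ESCITALOPRAM OXALATE", "LEXAPRO"), 0.014),
    DrugSpec("citalopram", ("CITALOPRAM", "CITALOPRAM HYDROBROMIDE", "CELEXA"), 0.013),
    DrugSpec("fluvoxamine", ("FLUVOXAMINE", "FLUVOXAMINE MALEATE", "LUVOX"), 0.003),
)

_BACKGROUND_DRUGS = (
    "IBUPROFEN", "METFORMIN", "LISINOPRIL", "OMEPRAZOLE", "ASPIRIN",
    "AMOXICILLIN", "WARFARIN", "INSULIN GLARGINE", "LEVOTHYROXINE", "PREDNISONE",
)

_STATIN_VERBATIMS = ("ATORVASTATIN CALCIUM", "SIMVASTATIN", "LIPITOR", "ROSUVASTATIN", "CRESTOR")

_DEFAULT_EVENTS: Mapping[str, float] = {
    "Rhabdomyolysis": 0.01,
    "Nausea": 0.08,
    "Headache": 0.06,
    "Dizziness": 0.05,
}

_COUNTRIES = ("US", "FR", "GB", "IT", "JP", "DE", "CA", "ES")
_COUNTRY_P = (0.35, 0.11, 0.11, 0.08, 0.08, 0.07, 0.06, 0.14)

_OUTCOME_P: Mapping[str, float] = {
    "HO": 0.45, "OT": 0.30, "LT": 0.10, "DE": 0.06, "DS": 0.04, "RI": 0.02, "CA": 0.01,
}


@dataclass
class SynthConfig:
    """Generative parameters; defaults are the package's study conditions."""

    seed: int
    n_cases: int = 50_000
    quarters: tuple[str, ...] = ("2022q1", "2022q2", "2022q3", "2022q4")
    drug_catalog: tuple[DrugSpec, ...] = _DEFAULT_DRUGS
    background_drugs: tuple[str, ...] = _BACKGROUND_DRUGS
    event_catalog: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_EVENTS))
    filler_pt: str = "Drug ineffective"
    signal_multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dup_rate: float = 0.2
    dup_same_day_rate: float = 0.02
    multi_ps_rate: float = 0.01
    comed_rate: float = 0.05
    age_missing_rate: float = 0.15
    sex_unknown_rate: float = 0.10
    event_dt_missing_rate: float = 0.20
    event_dt_partial_rate: float = 0.05
    start_dt_missing_rate: float = 0.10
    date_error_rate: float = 0.03
    onset_log_mu: float = 3.0  # ln(days); median ~20 d
    onset_log_sigma: float = 1.8
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: dict(_OUTCOME_P))

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not self.quarters:
            raise ValueError("at least one quarter is required")
        probs = [d.probability for d in self.drug_catalog]
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) > 1:
            raise ValueError("drug exposure probabilities must lie in [0,1] and sum to <= 1")
        rates = dict(
            dup_rate=self.dup_rate, dup_same_day_rate=self.dup_same_day_rate,
            multi_ps_rate=self.multi_ps_rate, comed_rate=self.comed_rate,
            age_missing_rate=self.age_missing_rate, sex_unknown_rate=self.sex_unknown_rate,
            event_dt_missing_rate=self.event_dt_missing_rate,
            event_dt_partial_rate=self.event_dt_partial_rate,
            start_dt_missing_rate=self.start_dt_missing_rate,
            date_error_rate=self.date_error_rate,
        )
        for name, p in {**rates, **dict(self.event_catalog)}.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability {name} = {p} outside [0, 1]")
        if self.dup_rate + self.dup_same_day_rate > 1:
            raise ValueError("dup_rate + dup_same_day_rate must be <= 1")
        for (d, e), lam in self.signal_multipliers.items():
            if lam < 0:
                raise ValueError(f"signal multiplier for ({d}, {e}) must be >= 0")
            if d not in {s.canonical for s in self.drug_catalog}:
                raise ValueError(f"signal multiplier references unknown drug {d!r}")
            if e not in self.event_catalog:
                raise ValueError(f"signal multiplier references unknown event {e!r}")


@dataclass
class GroundTruth:
    """Exact per-case bookkeeping of one simulated corpus (caseid terms)."""

    n_unique: int
    survivor_primaryid: dict[int, int]
    drug_cases: dict[str, set[int]]  # sole-PS target-drug caseids
    event_cases: dict[str, set[int]]
    statin_cases: set[int]
    multi_ps_cases: set[int]
    onset_days: dict[int, int]
    n_duplicate_emissions: int

    def drug_event_cases(self, drug: str, event: str) -> set[int]:
        return self.drug_cases[drug] & self.event_cases[event]

    def as_primaryids(self, caseids: set[int]) -> set[int]:
        """Translate caseid sets into surviving-report primaryid sets."""
        return {self.survivor_primaryid[c] for c in caseids}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_unique": self.n_unique,
            "n_duplicate_emissions": self.n_duplicate_emissions,
            "survivor_primaryid": {str(k): v for k, v in self.survivor_primaryid.items()},
            "drug_cases": {d: sorted(v) for d, v in self.drug_cases.items()},
            "event_cases": {e: sorted(v) for e, v in self.event_cases.items()},
            "statin_cases": sorted(self.statin_cases),
            "multi_ps_cases": sorted(self.multi_ps_cases),
            "onset_days": {str(k): v for k, v in self.onset_days.items()},
        }
        Path(path).write_text(json.dumps(payload))


def _quarter_bounds(quarters: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """(start dates, lengths in days) of each quarter as datetime64[D]."""
    starts = []
    lengths = []
    for q in quarters:
        year, qq = int(q[:4]), int(q[-1])
        start = np.datetime64(f"{year}-{(qq - 1) * 3 + 1:02d}-01", "D")
        if qq < 4:
            end = np.datetime64(f"{year}-{qq * 3 + 1:02d}-01", "D")
        else:
            end = np.datetime64(f"{year + 1}-01-01", "D")
        starts.append(start)
        lengths.append(int((end - start).astype(int)))
    return np.array(starts, dtype="datetime64[D]"), np.array(lengths)


def _yyyymmdd(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] -> 'YYYYMMDD' string array."""
    months = dates.astype("datetime64[M]")
    y = dates.astype("datetime64[Y]").astype(int) + 1970
    m = months.astype(int) % 12 + 1
    d = (dates - months).astype(int) + 1
    return (y * 10000 + m * 100 + d).astype(str)


def simulate(config: SynthConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Draw one corpus in memory.

    Returns the five tables (lower-case columns, integer ``primaryid``,
    everything else strings — the exact in-memory form the readers
    produce) and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    caseids = np.arange(1, n + 1, dtype=np.int64)
    pid1 = caseids * 100 + 1

    targets = config.drug_catalog
    n_targets = len(targets)
    target_names = [d.canonical for d in targets]
    p_drugs = np.array([d.probability for d in targets] + [1 - sum(d.probability for d in targets)])
    drug_idx = rng.choice(n_targets + 1, size=n, p=p_drugs)
    is_target = drug_idx < n_targets

    # event incidence, with per-drug signal multipliers
    event_names = list(config.event_catalog)
    lam = np.ones((n_targets + 1, len(event_names)))
    for (d, e), v in config.signal_multipliers.items():
        lam[target_names.index(d), event_names.index(e)] = v
    p_events = np.minimum(1.0, np.array([config.event_catalog[e] for e in event_names]) * lam[drug_idx])
    event_matrix = rng.random((n, len(event_names))) < p_events

    dup_u = rng.random(n)
    same_day_dup = dup_u < config.dup_same_day_rate
    later_dup = (~same_day_dup) & (dup_u < config.dup_same_day_rate + config.dup_rate)
    any_dup = same_day_dup | later_dup

    multi_ps = (rng.random(n) < config.multi_ps_rate) & is_target
    if n_targets < 2:  # no distinct second target exists
        multi_ps[:] = False
    second_idx = (drug_idx + 1 + rng.integers(0, max(n_targets - 1, 1), size=n)) % n_targets
    statin = rng.random(n) < config.comed_rate

    # dates: fda within a uniformly chosen quarter; therapy start before fda;
    # event = start + onset (log-normal days)
    qstarts, qlens = _quarter_bounds(config.quarters)
    qidx = rng.integers(0, len(config.quarters), size=n)
    fda = qstarts[qidx] + rng.integers(0, qlens[qidx]).astype("timedelta64[D]")
    onset = np.round(np.exp(rng.normal(config.onset_log_mu, config.onset_log_sigma, size=n))).astype(np.int64)
    start = fda - (onset + rng.integers(0, 60, size=n)).astype("timedelta64[D]")
    event = start + onset.astype("timedelta64[D]")
    date_err = rng.random(n) < config.date_error_rate
    event[date_err] = start[date_err] - rng.integers(1, 30, size=int(date_err.sum())).astype("timedelta64[D]")

    fda_s = _yyyymmdd(fda)
    start_s = _yyyymmdd(start)
    event_s = _yyyymmdd(event)
    start_s[rng.random(n) < config.start_dt_missing_rate] = ""
    ev_u = rng.random(n)
    event_s[ev_u < config.event_dt_missing_rate] = ""
    partial = (ev_u >= config.event_dt_missing_rate) & (
        ev_u < config.event_dt_missing_rate + config.event_dt_partial_rate
    )
    event_s[partial] = np.char.ljust(event_s[partial].astype("U6"), 6)

    # demographics
    age_years = np.clip(rng.normal(45, 20, size=n), 0, 100)
    unit_u = rng.random(n)
    age_val = np.round(age_years, 0).astype(np.int64).astype(str)
    age_cod = np.full(n, "YR", dtype="U3")
    mon = unit_u < 0.05
    age_val[mon] = np.round(age_years[mon] * 12).astype(np.int64).astype(str)
    age_cod[mon] = "MON"
    dec = (unit_u >= 0.05) & (unit_u < 0.10)
    age_val[dec] = np.round(age_years[dec] / 10).astype(np.int64).astype(str)
    age_cod[dec] = "DEC"
    age_gone = rng.random(n) < config.age_missing_rate
    age_val[age_gone] = ""
    age_cod[age_gone] = ""
    sex = rng.choice(np.array(["F", "M"]), size=n, p=[0.53, 0.47]).astype("U1")
    sex[rng.random(n) < config.sex_unknown_rate] = ""
    occp = rng.choice(np.array(["MD", "PH", "OT", "RN", "CN", "LW", ""]), size=n,
                      p=[0.35, 0.12, 0.18, 0.05, 0.15, 0.02, 0.13])
    country = rng.choice(np.array(_COUNTRIES), size=n, p=np.array(_COUNTRY_P))
    occr = country.copy()
    occr[rng.random(n) < 0.10] = ""

    demo = pd.DataFrame({
        "primaryid": pid1,
        "caseid": caseids.astype(str),
        "caseversion": np.full(n, "1"),
        "fda_dt": fda_s,
        "event_dt": event_s,
        "age": age_val,
        "age_cod": age_cod,
        "sex": sex,
        "occp_cod": occp,
        "reporter_country": country,
        "occr_country": occr,
    })

    # DRUG rows: seq 1 = PS drug, optional second PS, statin C, background C
    verbatim1 = np.empty(n, dtype=object)
    for i, spec in enumerate(targets):
        mask = drug_idx == i
        verbatim1[mask] = np.array(spec.verbatims, dtype=object)[
            rng.integers(0, len(spec.verbatims), size=int(mask.sum()))
        ]
    bg = ~is_target
    verbatim1[bg] = np.array(config.background_drugs, dtype=object)[
        rng.integers(0, len(config.background_drugs), size=int(bg.sum()))
    ]
    drug_parts = [pd.DataFrame({
        "primaryid": pid1, "caseid": caseids.astype(str), "drug_seq": "1",
        "role_cod": "PS", "drugname": verbatim1,
    })]
    if multi_ps.any():
        idx2 = second_idx[multi_ps]
        v2 = np.array([targets[i].verbatims[0] for i in idx2], dtype=object)
        drug_parts.append(pd.DataFrame({
            "primaryid": pid1[multi_ps], "caseid": caseids[multi_ps].astype(str),
            "drug_seq": "2", "role_cod": "PS", "drugname": v2,
        }))
    if statin.any():
        sv = np.array(_STATIN_VERBATIMS, dtype=object)[
            rng.integers(0, len(_STATIN_VERBATIMS), size=int(statin.sum()))
        ]
        drug_parts.append(pd.DataFrame({
            "primaryid": pid1[statin], "caseid": caseids[statin].astype(str),
            "drug_seq": "3", "role_cod": "C", "drugname": sv,
        }))
    n_bg = rng.choice(3, size=n, p=[0.50, 0.35, 0.15])
    for k in (1, 2):
        mask = n_bg >= k
        if mask.any():
            names = np.array(config.background_drugs, dtype=object)[
                rng.integers(0, len(config.background_drugs), size=int(mask.sum()))
            ]
            drug_parts.append(pd.DataFrame({
                "primaryid": pid1[mask], "caseid": caseids[mask].astype(str),
                "drug_seq": str(3 + k), "role_cod": "C", "drugname": names,
            }))
    drug = pd.concat(drug_parts, ignore_index=True)

    # REAC rows, with a filler PT for event-free cases
    reac_parts = []
    for j, ename in enumerate(event_names):
        mask = event_matrix[:, j]
        reac_parts.append(pd.DataFrame({
            "primaryid": pid1[mask], "caseid": caseids[mask].astype(str), "pt": ename,
        }))
    none_mask = ~event_matrix.any(axis=1)
    reac_parts.append(pd.DataFrame({
        "primaryid": pid1[none_mask], "caseid": caseids[none_mask].astype(str),
        "pt": config.filler_pt,
    }))
    reac = pd.concat(reac_parts, ignore_index=True)

    ther = pd.DataFrame({
        "primaryid": pid1, "caseid": caseids.astype(str), "dsg_drug_seq": "1",
        "start_dt": start_s, "end_dt": "",
    })

    outc_parts = []
    for code, p in config.outcome_probs.items():
        mask = rng.random(n) < p
        outc_parts.append(pd.DataFrame({
            "primaryid": pid1[mask], "caseid": caseids[mask].astype(str), "outc_cod": code,
        }))
    outc = pd.concat(outc_parts, ignore_index=True)

    # duplicate re-emissions: same caseid, version 2, same content
    dup_fda = fda[any_dup].copy()
    dup_fda[later_dup[any_dup]] += rng.integers(1, 180, size=int(later_dup.sum())).astype("timedelta64[D]")
    pid2 = caseids[any_dup] * 100 + 2
    pid_map = pd.Series(pid2, index=pid1[any_dup])
    demo_dup = demo[any_dup].copy()
    demo_dup["primaryid"] = pid2
    demo_dup["caseversion"] = "2"
    demo_dup["fda_dt"] = _yyyymmdd(dup_fda)
    demo = pd.concat([demo, demo_dup], ignore_index=True)

    tables = {"demo": demo, "drug": drug, "reac": reac, "ther": ther, "outc": outc}
    for t in ("drug", "reac", "ther", "outc"):
        df = tables[t]
        dup_rows = df[df["primaryid"].isin(pid_map.index)].copy()
        dup_rows["primaryid"] = dup_rows["primaryid"].map(pid_map).astype("int64")
        tables[t] = pd.concat([df, dup_rows], ignore_index=True)

    survivor = np.where(any_dup, caseids * 100 + 2, pid1)
    sole = is_target & ~multi_ps
    truth = GroundTruth(
        n_unique=n,
        survivor_primaryid={int(c): int(s) for c, s in zip(caseids, survivor)},
        drug_cases={
            name: set(caseids[sole & (drug_idx == i)].tolist())
            for i, name in enumerate(target_names)
        },
        event_cases={
            ename: set(caseids[event_matrix[:, j]].tolist())
            for j, ename in enumerate(event_names)
        },
        statin_cases=set(caseids[statin].tolist()),
        multi_ps_cases=set(caseids[multi_ps].tolist()),
        onset_days={int(c): int(o) for c, o in zip(caseids, onset)},
        n_duplicate_emissions=int(any_dup.sum()),
    )
    return tables, truth


def corpus_from_tables(tables: Mapping[str, pd.DataFrame]) -> Corpus:
    """Wrap simulated tables as an analysis-ready corpus (no file I/O)."""
    return Corpus(**{t: tables[t] for t in TABLE_NAMES},
                  orphans_dropped={t: 0 for t in TABLE_NAMES[1:]},
                  skipped_rows={t: 0 for t in TABLE_NAMES})


def write_corpus(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path, config: SynthConfig
) -> list[Path]:
    """Emit quarterly '$'-delimited files in the FAERS dialect.

    Rows are assigned to the quarter containing their report version's
    FDA date (clamped into the configured range for late duplicate
    re-emissions). Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qstarts, qlens = _quarter_bounds(config.quarters)
    demo = tables["demo"]
    fda = pd.to_datetime(demo["fda_dt"], format="%Y%m%d").to_numpy().astype("datetime64[D]")
    q_of_demo = np.clip(np.searchsorted(qstarts, fda, side="right") - 1, 0, len(qstarts) - 1)
    pid_quarter = pd.Series(q_of_demo, index=demo["primaryid"].to_numpy())

    paths = []
    for qi, q in enumerate(config.quarters):
        token = f"{q[2:4]}Q{q[-1]}"
        for t in TABLE_NAMES:
            df = tables[t]
            mask = (q_of_demo == qi) if t == "demo" else (
                df["primaryid"].map(pid_quarter).to_numpy() == qi
            )
            sub = df[mask]
            path = out_dir / f"{t.upper()}{token}.txt"
            lines = [
                "$".join(c.upper() for c in sub.columns),
                *("$".join(map(str, row)) for row in sub.itertuples(index=False, name=None)),
            ]
            path.write_text("\n".join(lines) + "\n")
            paths.append(path)
    return paths


def generate(config: SynthConfig, out_dir: str | Path | None = None
             ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate a corpus and, when ``out_dir`` is given, write the
    quarterly files plus a ``ground_truth.json`` sidecar."""
    tables, truth = simulate(config)
    if out_dir is not None:
        write_corpus(tables, out_dir, config)
        truth.to_json(Path(out_dir) / "ground_truth.json")
    return tables, truth


class Margins(NamedTuple):
    """2x2 margins: case count a, drug-set total, event total, database N."""

    a: int
    drug_total: Optional[int]
    event_total: int
    n: int


# Published screening counts of the source study's FAERS window
# (2004Q1-2022Q4): 16,011,277 deduplicated reports, 33,574 rhabdomyolysis
# reports, 151,660 SSRI-PS reports, 889 in the intersection; per-drug
# intersection counts from the case-series table. Per-drug exposure
# totals were not published, so those entries carry a only.
_CLASS_MARGINS = Margins(a=889, drug_total=151_660, event_total=33_574, n=16_011_277)
_PER_DRUG_A = {
    "sertraline": 288,
    "fluoxetine": 163,
    "paroxetine": 145,
    "escitalopram": 136,
    "citalopram": 129,
    "fluvoxamine": 28,
}


def published_margins() -> dict[str, Margins]:
    """Published SSRI/rhabdomyolysis screening margins, for driving the
    statistics layer without any corpus."""
    out = {"SSRIs": _CLASS_MARGINS}
    for drug, a in _PER_DRUG_A.items():
        out[drug] = Margins(a=a, drug_total=None,
                            event_total=_CLASS_MARGINS.event_total, n=_CLASS_MARGINS.n)
    return out
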