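"""Clinical stratification of an idiopathic-ASD cohort into the Phen1 endophenotype.

The endophenotype is defined by two clinical criteria applied after a genetic
exclusion screen:

1. head circumference (HC) at or above the 75th percentile on at least one
   physician-documented measure taken within the first 24 months of life, and
2. at least one well-characterised "flare" — an appreciable worsening of core
   behavioural symptoms during an immune challenge (fever, infection,
   vaccination, tooth loss, acute inflammation).

``classify_cohort`` reproduces the screening funnel: screened → documented HC
→ HC ≥ 75 → flare-assessable → Phen1, with the prevalence denominator being
every patient for whom *both* criteria could be assessed (flare-assessable
HC ≥ 75 patients plus documented HC < 75 patients, who are treated as
assessable unless explicitly flagged otherwise).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "IMMUNE_TRIGGERS",
    "GENETIC_SCREEN_STATES",
    "HCMeasure",
    "FlareEvent",
    "PatientRecord",
    "StratificationResult",
    "load_exclusion_panel",
    "genetic_exclusion",
    "hc_criterion",
    "flare_criterion",
    "classify_cohort",
    "select_non_phen1",
]

#: Trigger types that count as an immune challenge for the flare criterion.
IMMUNE_TRIGGERS = frozenset(
    {"fever", "infection", "vaccination", "tooth-loss", "acute-inflammation"}
)

GENETIC_SCREEN_STATES = frozenset(
    {
        "clear",
        "excluded_variant",
        "chromosomal_abnormality",
        "plasma_aa_abnormality",
        "not_done",
    }
)

HC_PERCENTILE_CUTOFF = 75.0
HC_AGE_CUTOFF_MONTHS = 24.0  # closed: a measure taken exactly at 24 months counts


@dataclass(frozen=True)
class HCMeasure:
    """A single head-circumference measurement, expressed as a growth percentile."""

    age_months: float
    percentile: float
    documented_by_physician: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_months) or self.age_months < 0:
            raise ValueError(f"age_months must be a non-negative real, got {self.age_months}")
        if not np.isfinite(self.percentile) or not (0.0 <= self.percentile <= 100.0):
            raise ValueError(f"percentile must lie in [0, 100], got {self.percentile}")


@dataclass(frozen=True)
class FlareEvent:
    """A reported behavioural-worsening episode and the immune trigger behind it."""

    trigger: str
    worsening: bool


@dataclass
class PatientRecord:
    """One screened individual.

    ``funnel_stage`` is an optional ground-truth label attached by the
    synthetic generator; the classifier never reads it.
    """

    id: str
    asd_diagnosis: bool = True
    hc_measures: list[HCMeasure] = field(default_factory=list)
    flare_assessable: bool = True
    flare_events: list[FlareEvent] = field(default_factory=list)
    genetic_screen: str = "clear"
    funnel_stage: str | None = None

    def __post_init__(self) -> None:
        if self.genetic_screen not in GENETIC_SCREEN_STATES:
            raise ValueError(
                f"unknown genetic_screen state {self.genetic_screen!r}; "
                f"expected one of {sorted(GENETIC_SCREEN_STATES)}"
            )

    def max_documented_percentile(self) -> float | None:
        """Maximum HC percentile among physician-documented in-window measures."""
        vals = [
            m.percentile
            for m in self.hc_measures
            if m.documented_by_physician and m.age_months <= HC_AGE_CUTOFF_MONTHS
        ]
        return max(vals) if vals else None


@dataclass
class StratificationResult:
    """Screening-funnel counts, per-patient labels and the observed prevalence."""

    n_screened: int
    n_documented_hc: int
    n_hc_ge75: int
    n_flare_assessable_hc75: int
    n_phen1: int
    n_both_assessable: int
    prevalence: float
    labels: dict[str, str]

    @property
    def pct_documented(self) -> float:
        return 100.0 * self.n_documented_hc / self.n_screened

    @property
    def pct_hc_ge75(self) -> float:
        return 100.0 * self.n_hc_ge75 / self.n_documented_hc

    def to_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "n_documented_hc": self.n_documented_hc,
            "n_hc_ge75": self.n_hc_ge75,
            "n_flare_assessable_hc75": self.n_flare_assessable_hc75,
            "n_phen1": self.n_phen1,
            "n_both_assessable": self.n_both_assessable,
            "prevalence": self.prevalence,
            "pct_documented": self.pct_documented,
            "pct_hc_ge75": self.pct_hc_ge75,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def load_exclusion_panel() -> list[str]:
    """Gene symbols of the packaged ASD-associated exclusion panel."""
    text = (
        resources.files("endophen.resources")
        .joinpath("asd_exclusion_panel.txt")
        .read_text()
    )
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def genetic_exclusion(
    record: PatientRecord,
    panel: list[str] | None = None,
    not_done: str = "flag",
) -> bool:
    """Return True when the genetic screen excludes the patient.

    Any non-clear screen result (a pathogenic variant in a panel gene, a major
    chromosomal abnormality, or abnormal plasma amino-acid levels) excludes.
    Patients whose screen was never run are never silently passed: with
    ``not_done="flag"`` (default) they are flagged as excluded pending a
    screen; with ``not_done="error"`` a ``ValueError`` is raised.
    """
    if panel is None:
        panel = load_exclusion_panel()
    if not panel:
        raise ValueError("exclusion panel must be non-empty")
    if record.genetic_screen == "clear":
        return False
    if record.genetic_screen == "not_done":
        if not_done == "error":
            raise ValueError(f"patient {record.id}: genetic screen not done")
        if not_done != "flag":
            raise ValueError(f"unknown not_done policy {not_done!r}")
        return True
    return True


def hc_criterion(record: PatientRecord) -> str:
    """Evaluate the head-circumference criterion.

    Returns ``"undocumented"`` when no physician-documented measure exists
    within the first 24 months of life; otherwise ``"positive"`` iff any such
    measure reaches the 75th percentile (boundary inclusive).
    """
    mx = record.max_documented_percentile()
    if mx is None:
        return "undocumented"
    return "positive" if mx >= HC_PERCENTILE_CUTOFF else "negative"


def flare_criterion(record: PatientRecord, systematic: bool = False) -> str:
    """Evaluate the immune-flare criterion.

    ``"unassessable"`` when the medical record does not allow assessment.
    By default the criterion is positive when at least one immune-challenge
    event is accompanied by behavioural worsening. ``systematic=True``
    switches to the stricter reading under which *every* immune-challenge
    episode must show worsening.
    """
    for ev in record.flare_events:
        if ev.trigger not in IMMUNE_TRIGGERS:
            raise ValueError(
                f"patient {record.id}: unknown flare trigger {ev.trigger!r}; "
                f"expected one of {sorted(IMMUNE_TRIGGERS)}"
            )
    if not record.flare_assessable:
        return "unassessable"
    worsened = [ev.worsening for ev in record.flare_events]
    if systematic:
        return "positive" if worsened and all(worsened) else "negative"
    return "positive" if any(worsened) else "negative"


def classify_cohort(
    records: list[PatientRecord], systematic_flares: bool = False
) -> StratificationResult:
    """Run the full screening funnel over a cohort.

    Funnel: screened → documented HC → HC ≥ 75 → flare-assessable → Phen1.
    The prevalence denominator counts every patient for whom both criteria
    were assessable: flare-assessable HC ≥ 75 patients plus documented
    HC < 75 patients (assumed assessable unless their ``flare_assessable``
    flag says otherwise).
    """
    if not records:
        raise ValueError("cannot classify an empty cohort")
    dup = [k for k, c in Counter(r.id for r in records).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate patient ids: {dup}")

    labels: dict[str, str] = {}
    n_documented = n_ge75 = n_assessable75 = n_phen1 = n_lt75_assessable = 0
    for r in records:
        if r.genetic_screen != "clear":
            labels[r.id] = "excluded"
            continue
        hc = hc_criterion(r)
        if hc == "undocumented":
            labels[r.id] = "excluded"
            continue
        n_documented += 1
        if hc == "negative":
            if r.flare_assessable:
                n_lt75_assessable += 1
            labels[r.id] = "nonPhen1"
            continue
        n_ge75 += 1
        flare = flare_criterion(r, systematic=systematic_flares)
        if flare == "unassessable":
            labels[r.id] = "unassessable"
            continue
        n_assessable75 += 1
        if flare == "positive":
            n_phen1 += 1
            labels[r.id] = "Phen1"
        else:
            labels[r.id] = "nonPhen1"

    n_both = n_assessable75 + n_lt75_assessable
    if n_both == 0:
        raise ValueError(
            "prevalence undefined: no patient has both criteria assessable"
        )
    return StratificationResult(
        n_screened=len(records),
        n_documented_hc=n_documented,
        n_hc_ge75=n_ge75,
        n_flare_assessable_hc75=n_assessable75,
        n_phen1=n_phen1,
        n_both_assessable=n_both,
        prevalence=n_phen1 / n_both,
        labels=labels,
    )


def select_non_phen1(
    records: list[PatientRecord], n: int, seed: int | None = None
) -> list[PatientRecord]:
    """Sample comparison (non-Phen1) patients with an even spread of maximum HC.

    Eligible patients have a documented maximum HC percentile below 75 and a
    clear genetic screen. The selection is stratified into the three lower HC
    terciles — [0, 25), [25, 50), [50, 75) — aiming at one third each; when n
    is not divisible by 3 the remainder is assigned round-robin starting from
    the lowest tercile.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    edges = [(0.0, 25.0), (25.0, 50.0), (50.0, 75.0)]
    pools: list[list[PatientRecord]] = [[], [], []]
    for r in records:
        if r.genetic_screen != "clear":
            continue
        mx = r.max_documented_percentile()
        if mx is None or mx >= HC_PERCENTILE_CUTOFF:
            continue
        for t, (lo, hi) in enumerate(edges):
            if lo <= mx < hi:
                pools[t].append(r)
                break
    quotas = [n // 3] * 3
    for i in range(n % 3):
        quotas[i] += 1  # remainder round-robin from the lowest tercile
    chosen: list[PatientRecord] = []
    names = ["<25", "[25,50)", "[50,75)"]
    for t, (pool, q) in enumerate(zip(pools, quotas)):
        if len(pool) < q:
            raise ValueError(
                f"insufficient eligible records in HC tercile {names[t]}: "
                f"need {q}, have {len(pool)}"
            )
        idx = rng.choice(len(pool), size=q, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return chosen
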