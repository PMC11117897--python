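"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators produce, from a single seeded generator per call:

* a screening cohort (with a deterministic fixture mode that reproduces the
  published funnel counts 313 / 89 / 46 / 41 / 20 exactly, randomising only
  patient attributes within each funnel stratum),
* a negative-binomial RNA-seq count matrix with technical replicates and a
  planted up-regulated TF-target gene set,
* a drug library with one planted signature reverser and one mimicker among
  otherwise random drugs, and
* PM-M-style 96-well plate absorbance data with group-specific compound
  effects and a db-cAMP dose response confined to configured groups.

Defaults mirror the study design: funnel proportions from the screening of
313 records, a 10 + 10 subject expression cohort with two technical
replicates each, and a 2,100-drug library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import CountMatrix
from .drugsim import DrugSignature
from .enrich import GeneSet
from .plates import PlateAssay, dbcamp_dose, load_plate_layout
from .stratify import FlareEvent, HCMeasure, PatientRecord

__all__ = [
    "CohortConfig",
    "ExpressionSimConfig",
    "DrugLibraryConfig",
    "PlateSimConfig",
    "ExpressionGroundTruth",
    "DrugLibrary",
    "gen_cohort",
    "fixture_cohort",
    "gen_expression",
    "gen_drug_library",
    "gen_plates",
]

# published funnel: screened / documented HC / HC>=75 / flare-assessable / Phen1
FUNNEL_COUNTS = (313, 89, 46, 41, 20)


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass
class CohortConfig:
    """Bernoulli-chain parameters of the screening funnel.

    Defaults are the observed stage-to-stage proportions of the published
    screen (89/313 documented, 46/89 at or above the 75th percentile, 41/46
    flare-assessable, 20/41 flare-positive).
    """

    n_patients: int = 313
    p_documented_hc: float = 89 / 313
    p_hc_ge75_given_documented: float = 46 / 89
    p_flare_assessable_given_hc75: float = 41 / 46
    p_flare_positive_given_assessable: float = 20 / 41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        _check_prob("p_documented_hc", self.p_documented_hc)
        _check_prob("p_hc_ge75_given_documented", self.p_hc_ge75_given_documented)
        _check_prob(
            "p_flare_assessable_given_hc75", self.p_flare_assessable_given_hc75
        )
        _check_prob(
            "p_flare_positive_given_assessable", self.p_flare_positive_given_assessable
        )


def _make_record(rng: np.random.Generator, pid: str, stage: str) -> PatientRecord:
    """Randomise patient attributes within a fixed funnel stratum."""
    measures: list[HCMeasure] = []
    assessable = True
    events: list[FlareEvent] = []
    if stage == "undocumented":
        # either no HC on file or only an out-of-window / undocumented measure
        mode = rng.integers(3)
        if mode == 1:
            measures = [HCMeasure(float(rng.uniform(25, 60)), float(rng.uniform(1, 99)))]
        elif mode == 2:
            measures = [
                HCMeasure(
                    float(rng.uniform(0, 24)),
                    float(rng.uniform(1, 99)),
                    documented_by_physician=False,
                )
            ]
    elif stage == "documented_lt75":
        for _ in range(int(rng.integers(1, 4))):
            measures.append(
                HCMeasure(float(rng.uniform(0, 24)), float(rng.uniform(1, 74.9)))
            )
    else:  # HC >= 75 strata
        measures.append(
            HCMeasure(float(rng.uniform(0, 24)), float(rng.uniform(75, 99.5)))
        )
        if rng.random() < 0.5:
            measures.append(
                HCMeasure(float(rng.uniform(0, 24)), float(rng.uniform(1, 99.5)))
            )
        if stage == "hc75_unassessable":
            assessable = False
        elif stage == "hc75_no_flare":
            if rng.random() < 0.3:  # an event on record, but without worsening
                events.append(FlareEvent("fever", False))
        elif stage == "phen1":
            triggers = ["fever", "infection", "vaccination", "tooth-loss", "acute-inflammation"]
            for _ in range(int(rng.integers(1, 3))):
                events.append(FlareEvent(triggers[int(rng.integers(5))], True))
    return PatientRecord(
        id=pid,
        hc_measures=measures,
        flare_assessable=assessable,
        flare_events=events,
        funnel_stage=stage,
    )


def gen_cohort(config: CohortConfig, fixture: bool = False) -> list[PatientRecord]:
    """Generate a screening cohort.

    With ``fixture=True`` the funnel strata sizes are hard-wired to the
    published counts (313 screened, 89 documented, 46 HC ≥ 75, 41 assessable,
    20 flare-positive; the 43 documented HC < 75 patients all
    flare-assessable) and only within-stratum attributes are randomised, so
    the funnel is reproduced exactly. Otherwise each patient walks the
    Bernoulli chain given by the config probabilities.
    """
    rng = np.random.default_rng(config.seed)
    stages: list[str] = []
    if fixture:
        n_s, n_doc, n_75, n_ass, n_pos = FUNNEL_COUNTS
        stages += ["undocumented"] * (n_s - n_doc)
        stages += ["documented_lt75"] * (n_doc - n_75)
        stages += ["hc75_unassessable"] * (n_75 - n_ass)
        stages += ["hc75_no_flare"] * (n_ass - n_pos)
        stages += ["phen1"] * n_pos
    else:
        for _ in range(config.n_patients):
            if rng.random() >= config.p_documented_hc:
                stages.append("undocumented")
            elif rng.random() >= config.p_hc_ge75_given_documented:
                stages.append("documented_lt75")
            elif rng.random() >= config.p_flare_assessable_given_hc75:
                stages.append("hc75_unassessable")
            elif rng.random() >= config.p_flare_positive_given_assessable:
                stages.append("hc75_no_flare")
            else:
                stages.append("phen1")
    return [
        _make_record(rng, f"PT{i + 1:04d}", stage) for i, stage in enumerate(stages)
    ]


def fixture_cohort(seed: int = 0) -> list[PatientRecord]:
    """The deterministic published-funnel cohort (counts 313/89/46/41/20)."""
    return gen_cohort(CohortConfig(seed=seed), fixture=True)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimConfig:
    """NB count simulation mirroring the 10 + 10 blood RNA-seq design.

    ``target_set_size`` genes (the planted TF-target set) receive a log2 fold
    change drawn from N(planted_log2fc_mean, planted_log2fc_sd) in the Phen1
    group; a ``fraction_background_de`` share of the remaining genes gets a
    background effect from N(0, 1). Technical replicates are independent NB
    redraws from the same subject-level mean.
    """

    n_genes: int = 5000
    n_per_group: int = 10
    n_tech_reps: int = 2
    dispersion_range: tuple = (0.05, 0.5)
    baseline_mean_log_range: tuple = (0.5, 3.0)  # log10 of the mean count
    target_set_size: int = 100
    planted_log2fc_mean: float = 2.0
    planted_log2fc_sd: float = 0.3
    fraction_background_de: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        if not (0 <= self.target_set_size < self.n_genes):
            raise ValueError("target_set_size must be < n_genes")
        if self.dispersion_range[0] <= 0 or self.dispersion_range[1] < self.dispersion_range[0]:
            raise ValueError("dispersion_range must be a positive interval")
        _check_prob("fraction_background_de", self.fraction_background_de)


@dataclass
class ExpressionGroundTruth:
    log2fc: pd.Series  # true per-gene effect (Phen1 over nonPhen1)
    target_set: GeneSet | None  # None when no target genes were planted
    background_de_genes: list
    dispersions: pd.Series
    base_means: pd.Series


def gen_expression(
    config: ExpressionSimConfig,
) -> tuple[CountMatrix, ExpressionGroundTruth]:
    """Simulate a gene × sample NB count matrix with a planted signature."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(G)], name="gene")

    lo, hi = config.baseline_mean_log_range
    base = 10.0 ** rng.uniform(lo, hi, size=G)
    d_lo, d_hi = config.dispersion_range
    disp = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi), size=G))

    lfc = np.zeros(G)
    target_idx = rng.choice(G, size=config.target_set_size, replace=False)
    lfc[target_idx] = rng.normal(
        config.planted_log2fc_mean, config.planted_log2fc_sd, size=config.target_set_size
    )
    rest = np.setdiff1d(np.arange(G), target_idx)
    bg_mask = rng.random(rest.size) < config.fraction_background_de
    bg_idx = rest[bg_mask]
    lfc[bg_idx] = rng.normal(0.0, 1.0, size=bg_idx.size)

    subjects = [f"P{i + 1:02d}" for i in range(config.n_per_group)] + [
        f"N{i + 1:02d}" for i in range(config.n_per_group)
    ]
    group = {s: ("Phen1" if s.startswith("P") else "nonPhen1") for s in subjects}

    cols, rep_map = [], {}
    blocks = []
    for s in subjects:
        mu_subj = base * np.power(2.0, lfc * (group[s] == "Phen1"))
        for r in range(config.n_tech_reps):
            sample = f"{s}_rep{r + 1}"
            cols.append(sample)
            rep_map[sample] = s
            lib = rng.uniform(0.7, 1.4)  # per-sample library-size factor
            mu = mu_subj * lib
            n_param = 1.0 / disp
            p_param = n_param / (n_param + mu)
            blocks.append(rng.negative_binomial(n_param, p_param))
    counts = pd.DataFrame(
        np.column_stack(blocks), index=genes, columns=cols, dtype=np.int64
    )
    cm = CountMatrix(
        counts=counts,
        replicate_map=pd.Series(rep_map),
        subject_group=pd.Series(group),
    )
    truth = ExpressionGroundTruth(
        log2fc=pd.Series(lfc, index=genes),
        target_set=(
            GeneSet("TF_TARGETS", frozenset(genes[target_idx]), "planted")
            if len(target_idx)
            else None
        ),
        background_de_genes=list(genes[bg_idx]),
        dispersions=pd.Series(disp, index=genes),
        base_means=pd.Series(base, index=genes),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# drug library


@dataclass
class DrugLibraryConfig:
    """Synthetic drug library with one planted reverser and one mimicker."""

    n_drugs: int = 2100
    n_cell_lines: int = 3
    n_genes: int = 978
    reverser_strength: float = 0.8
    mimicker_strength: float = 0.8
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 3:
            raise ValueError("n_drugs must be >= 3")
        for name in ("reverser_strength", "mimicker_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DrugLibrary:
    signatures: list  # of DrugSignature
    universe: list
    reverser: str
    mimicker: str

    def __len__(self) -> int:
        return len(self.signatures)


def _rank_genes(genes: np.ndarray, score: np.ndarray) -> list:
    # rank 1 = highest score; ties broken by gene id
    order = np.lexsort((genes, -score))
    return list(genes[order])


def gen_drug_library(
    config: DrugLibraryConfig, disease_up: GeneSet, disease_down: GeneSet
) -> DrugLibrary:
    """Simulate per-cell-line drug rankings around a disease signature.

    The planted reverser pushes the disease's down genes toward its
    up-regulated end and the up genes toward the bottom (signal weight
    ``reverser_strength``, residual weight ``1 − strength`` of standard
    normal noise); the mimicker does the opposite. Every cell-line ranking
    additionally receives N(0, noise_sd) perturbations. All other drugs are
    pure noise.
    """
    if set(disease_up.members) & set(disease_down.members):
        raise ValueError("disease up and down sets overlap")
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)], dtype=object)
    universe = set(genes)
    for gs in (disease_up, disease_down):
        missing = set(gs.members) - universe
        if missing:
            raise ValueError(
                f"gene set {gs.name!r} not contained in the simulated universe "
                f"(e.g. {sorted(missing)[:5]})"
            )
    signal = np.zeros(config.n_genes)
    up_mask = np.isin(genes, list(disease_up.members))
    down_mask = np.isin(genes, list(disease_down.members))
    signal[down_mask] = 1.0  # a reverser up-regulates the disease's down genes
    signal[up_mask] = -1.0
    cell_lines = [f"CL{c + 1}" for c in range(config.n_cell_lines)]

    signatures = []
    for d in range(config.n_drugs):
        if d == 0:
            name, latent = "planted_reverser", (
                config.reverser_strength * signal
                + (1.0 - config.reverser_strength) * rng.normal(size=config.n_genes)
            )
        elif d == 1:
            name, latent = "planted_mimicker", (
                -config.mimicker_strength * signal
                + (1.0 - config.mimicker_strength) * rng.normal(size=config.n_genes)
            )
        else:
            name, latent = f"drug_{d:04d}", rng.normal(size=config.n_genes)
        rankings = {
            cl: _rank_genes(
                genes, latent + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            )
            for cl in cell_lines
        }
        signatures.append(DrugSignature(name=name, rankings=rankings))
    return DrugLibrary(
        signatures=signatures,
        universe=list(genes),
        reverser="planted_reverser",
        mimicker="planted_mimicker",
    )


# ---------------------------------------------------------------------------
# plates


def _default_compound_effects() -> dict:
    """Group-specific NADH shifts emulating the published metabolic contrasts.

    Phen1 cell lines metabolise sugar phosphates and sugars less and purine
    nucleosides / mono-methyl succinate more; non-Phen1 shows a milder sugar
    deficit.
    """
    sugars_phen1 = [
        "D-glucose-6-phosphate",
        "D-glucose-1-phosphate",
        "D-glucose",
        "D-mannose",
        "D-fructose-6-phosphate",
        "D-galactose",
    ]
    up_phen1 = ["adenosine", "inosine", "mono-methyl succinate"]
    eff: dict[str, dict[str, float]] = {}
    for c in sugars_phen1:
        eff[c] = {"Phen1": -0.15}
    for c in ["D-glucose-1-phosphate", "D-glucose", "D-fructose-6-phosphate"]:
        eff[c]["nonPhen1"] = -0.08
    for c in up_phen1:
        eff[c] = {"Phen1": +0.15}
    return eff


@dataclass
class PlateSimConfig:
    """PM-M plate simulation.

    ``group_sizes`` default to the study's cell-line counts (20 TD, 19
    non-Phen1, 17 Phen1). ``compound_effects`` maps compound → per-group mean
    shift of the NADH proxy; ``dose_slope_by_group`` gives the fractional
    NADH increase across the db-cAMP dose series on the PM-M6 plate (zero for
    groups without a dose response).
    """

    group_sizes: dict = field(
        default_factory=lambda: {"TD": 20, "nonPhen1": 19, "Phen1": 17}
    )
    compound_effects: dict = field(default_factory=_default_compound_effects)
    blank_mean: float = 0.08
    blank_sd: float = 0.02
    dose_levels: tuple = (0, 1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000)
    dose_slope_by_group: dict = field(
        default_factory=lambda: {"TD": 0.0, "nonPhen1": 0.0, "Phen1": 0.35}
    )
    base_absorbance: float = 0.45
    well_sd: float = 0.05
    background_mean: float = 0.05
    background_sd: float = 0.01
    n_blank_plates: int = 3
    plates: tuple = ("PM-M1", "PM-M6")
    treatment: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group_sizes must be positive")
        if self.blank_sd < 0:
            raise ValueError("blank_sd must be >= 0")


def gen_plates(config: PlateSimConfig) -> list[PlateAssay]:
    """Simulate dual-wavelength PM-M plate reads for every cell line.

    Cell plates draw each compound well around ``base_absorbance`` plus the
    configured group shift; blank wells, and all wells of the
    ``n_blank_plates`` no-cell plates (group ``"blank"``), draw from the
    blank distribution regardless of group. The PM-M6 row-A dose series
    scales the glucose signal by ``1 + slope · dose_fraction`` for the cell
    line's group, with dose_fraction the log-dose position in the series.
    """
    rng = np.random.default_rng(config.seed)
    layouts = {p: load_plate_layout(p) for p in config.plates}
    # effect keys are validated against every packaged layout, so a config
    # carrying PM-M1 effects can still generate only the PM-M6 plate
    known = {
        c
        for pid in ("PM-M1", "PM-M2", "PM-M3", "PM-M4", "PM-M6")
        for c in load_plate_layout(pid).values
    } | {"blank"}
    for comp in config.compound_effects:
        if comp not in known:
            raise ValueError(f"unknown compound key in compound_effects: {comp!r}")

    max_log = np.log1p(max(config.dose_levels))
    assays: list[PlateAssay] = []

    def one_plate(plate_id, cell_line, group, is_blank_plate):
        wells = {}
        slope = config.dose_slope_by_group.get(group, 0.0)
        for well, comp in layouts[plate_id].items():
            bg = max(rng.normal(config.background_mean, config.background_sd), 0.0)
            dose = dbcamp_dose(comp)
            if is_blank_plate or comp == "blank":
                sig = rng.normal(config.blank_mean, config.blank_sd)
            elif dose is not None:
                frac = np.log1p(dose) / max_log
                sig = rng.normal(
                    config.base_absorbance * (1.0 + slope * frac), config.well_sd
                )
            else:
                shift = config.compound_effects.get(comp, {}).get(group, 0.0)
                sig = rng.normal(config.base_absorbance + shift, config.well_sd)
            a750 = bg
            a590 = max(bg + sig, 0.0)
            wells[well] = (comp, float(a590), float(a750))
        return PlateAssay(
            plate_id=plate_id,
            wells=wells,
            cell_line_id=cell_line,
            group=group,
            treatment=config.treatment,
        )

    prefixes = {"TD": "TD", "nonPhen1": "NP", "Phen1": "P"}
    for group, n in config.group_sizes.items():
        pref = prefixes.get(group, group[:2].upper())
        for i in range(n):
            cl = f"{pref}{i + 1:02d}"
            for plate_id in config.plates:
                assays.append(one_plate(plate_id, cl, group, False))
    for b in range(config.n_blank_plates):
        for plate_id in config.plates:
            assays.append(one_plate(plate_id, f"blank{b + 1:02d}", "blank", True))
    return assays
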