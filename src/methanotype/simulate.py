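"""Synthetic study-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: 1 Hz sniffer CH4
traces with Poisson eructation pulses diluted by ambient air, Dirichlet-
multinomial OTU count tables with two planted community states, qPCR
standard-curve and sample Cq tables, and per-cow feed/feces/milk/VFA tables
consistent with a chosen true digestibility.  Each generator returns its
ground truth alongside the data, and all randomness flows from one explicit
seed per call through splittable child streams, so identical inputs give
bit-identical outputs.

The defaults emulate a dairy-herd methane study: a selected cohort of
persistent low / medium / high emitters (group means about 280, 315 and
350 g CH4/day), 14-day measurement windows with about 2.5 robot milkings per
day, triplicate 16S libraries per rumen sample, and two planted community
states (L and H) whose differential OTUs, archaeal clade splits and VFA
profiles follow the magnitudes reported for low- and high-emitting cows.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from ._rng import child_rng
from .community import OtuTable
from .qpcr import StandardCurve
from .sniffer import DEFAULT_STATION_GAIN, GasTrace

__all__ = [
    "HerdConfig",
    "TraceParams",
    "CommunityParams",
    "PhenotypeTables",
    "make_herd",
    "gen_gas_trace",
    "render_trace",
    "default_community_params",
    "gen_otu_table",
    "gen_qpcr_data",
    "default_qpcr_truth",
    "gen_phenotype_tables",
    "DEFAULT_VFA_STATE_MEANS",
    "DEFAULT_DIGESTIBILITY",
]


# ---------------------------------------------------------------------------
# herd
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class HerdConfig:
    """Study design: cows, periods, milking schedule and planted truth.

    ``true_rates`` holds each cow's true emission rate (g CH4/day);
    ``true_groups`` the planted emitter tertile (L/M/H); and
    ``cluster_assignment`` the planted rumen community state (L/H) — medium
    emitters carry either community state, mirroring their occurrence in both
    observed clusters.
    """

    n_cows: int
    true_rates: pd.Series
    cluster_assignment: pd.Series
    true_groups: pd.Series | None = None
    n_periods: int = 3
    sessions_per_day: float = 2.5
    period_days: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows <= 0 or self.n_periods <= 0 or self.period_days <= 0:
            raise ValueError("n_cows, n_periods and period_days must be positive")
        if self.sessions_per_day <= 0:
            raise ValueError("sessions_per_day must be positive")
        if len(self.true_rates) != self.n_cows:
            raise ValueError("true_rates must cover every cow")
        if (self.true_rates <= 0).any():
            raise ValueError("true emission rates must be strictly positive")
        missing = set(self.true_rates.index) - set(self.cluster_assignment.index)
        if missing:
            raise ValueError(f"cluster_assignment missing cows: {sorted(missing)}")
        bad = set(self.cluster_assignment.unique()) - {"L", "H"}
        if bad:
            raise ValueError(f"cluster labels must be 'L' or 'H', got {sorted(bad)}")

    @property
    def cows(self) -> list[str]:
        return list(self.true_rates.index)

    @property
    def periods(self) -> list[int]:
        return list(range(1, self.n_periods + 1))


#: Default emitter-group mean rates (g CH4/day) and within-group SD for the
#: selected persistent-emitter cohort the generator emulates.
_GROUP_RATE_MEANS = {"L": 280.0, "M": 315.0, "H": 350.0}
_GROUP_RATE_SD = 8.0


def make_herd(
    n_cows: int = 21,
    n_periods: int = 3,
    seed: int = 0,
    sessions_per_day: float = 2.5,
    period_days: int = 14,
    group_means: Mapping[str, float] | None = None,
    group_sd: float = _GROUP_RATE_SD,
) -> HerdConfig:
    """Build a default herd of persistent low/medium/high emitters.

    Cows are split into three near-equal emitter tertiles; true rates are
    drawn around the group means.  Community state is L for low emitters,
    H for high emitters, and random for medium emitters.
    """
    means = dict(_GROUP_RATE_MEANS if group_means is None else group_means)
    rng = child_rng(seed, "herd")
    cows = [f"cow{i + 1:02d}" for i in range(n_cows)]
    sizes = [len(part) for part in np.array_split(np.arange(n_cows), 3)]
    groups = ["L"] * sizes[0] + ["M"] * sizes[1] + ["H"] * sizes[2]
    rates = np.concatenate(
        [
            means[g] + group_sd * rng.standard_normal(n)
            for g, n in zip(["L", "M", "H"], sizes)
        ]
    )
    rates = np.clip(rates, 1.0, None)
    clusters = [
        g if g in ("L", "H") else ("L" if rng.random() < 0.5 else "H") for g in groups
    ]
    return HerdConfig(
        n_cows=n_cows,
        true_rates=pd.Series(rates, index=cows, name="true_rate"),
        cluster_assignment=pd.Series(clusters, index=cows, name="cluster"),
        true_groups=pd.Series(groups, index=cows, name="group"),
        n_periods=n_periods,
        sessions_per_day=sessions_per_day,
        period_days=period_days,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# gas traces
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TraceParams:
    """Physics of a synthetic sniffer trace.

    The baseline is ambient barn air: a level plus a bounded AR(1) drift plus
    white noise.  Eructation pulses arrive as a Poisson process; each pulse
    has a piecewise shape (linear rise, exponential decay) whose undiluted
    area is proportional to the cow's true rate, divided by the ambient-air
    dilution factor before it reaches the analyser.
    """

    baseline_level: float = 300.0  # mg/kg
    baseline_drift_sd: float = 10.0  # mg/kg, stationary SD of the AR(1) drift
    noise_sd: float = 8.0  # mg/kg white noise
    eructation_rate: float = 1.5  # events per minute
    peak_shape: tuple[float, float] = (3.0, 6.0)  # (rise s, decay time-constant s)
    dilution_factor: float = 2.5  # >= 1
    sampling_hz: float = 1.0
    amplitude_cv: float = 0.15  # event-to-event pulse-area variability
    station_gain: float = DEFAULT_STATION_GAIN  # g/day per undiluted index unit
    drift_ar: float = 0.99  # AR(1) coefficient of the baseline drift

    def __post_init__(self) -> None:
        if self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must be >= 1")
        if self.eructation_rate <= 0:
            raise ValueError("eructation_rate must be positive")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")

    @property
    def pulse_unit_area(self) -> float:
        """Area of a unit-amplitude pulse: rise/2 + decay time-constant."""
        rise, decay = self.peak_shape
        return rise / 2.0 + decay


def _baseline(params: TraceParams, n: int, rng: np.random.Generator) -> np.ndarray:
    rho = params.drift_ar
    innov_sd = params.baseline_drift_sd * np.sqrt(1.0 - rho**2)
    drift = np.empty(n)
    x = params.baseline_drift_sd * rng.standard_normal()
    for i in range(n):
        x = rho * x + innov_sd * rng.standard_normal()
        drift[i] = x
    np.clip(drift, -3 * params.baseline_drift_sd, 3 * params.baseline_drift_sd, out=drift)
    noise = params.noise_sd * rng.standard_normal(n)
    return params.baseline_level + drift + noise


def render_trace(
    event_times: np.ndarray,
    amplitudes: np.ndarray,
    params: TraceParams,
    duration: float,
    seed: int,
    cow_id: str = "",
    session_id: str = "",
) -> GasTrace:
    """Render a trace from explicit pulse times and amplitudes (mg/kg).

    Low-level entry point used both by :func:`gen_gas_trace` and by tests
    that plant events directly (e.g. sub-threshold pulses).
    """
    if duration < 60:
        raise ValueError("duration must be at least 60 s")
    event_times = np.asarray(event_times, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    rng = child_rng(seed, "trace", cow_id, session_id)
    n = int(round(duration * params.sampling_hz))
    t = np.arange(n) / params.sampling_hz
    c = _baseline(params, n, rng)

    rise, decay = params.peak_shape
    support = rise + 8.0 * decay
    for t0, amp in zip(event_times, amplitudes):
        i0 = max(int(np.floor(t0 * params.sampling_hz)), 0)
        i1 = min(int(np.ceil((t0 + support) * params.sampling_hz)) + 1, n)
        if i0 >= n:
            continue
        u = t[i0:i1] - t0
        shape = np.where(
            u < 0, 0.0, np.where(u <= rise, u / rise, np.exp(-(u - rise) / decay))
        )
        c[i0:i1] += amp * shape

    events = pd.DataFrame(
        {
            "time_s": event_times,
            "amplitude": amplitudes,
            "area": amplitudes * params.pulse_unit_area,
        }
    )
    return GasTrace(
        cow_id=cow_id,
        session_id=session_id,
        t=t,
        c=np.clip(c, 0.0, None),
        events=events,
    )


def gen_gas_trace(
    cow_rate: float,
    params: TraceParams,
    duration: float,
    seed: int,
    cow_id: str = "",
    session_id: str = "",
) -> GasTrace:
    """Simulate one milking session's 1 Hz CH4 trace for a cow.

    Eructations arrive as a Poisson process at ``params.eructation_rate``.
    The expected undiluted pulse area per event is
    ``cow_rate / (station_gain * eructation_rate)``, so the expected
    undiluted CH4 index (frequency x mean area) equals
    ``cow_rate / station_gain`` and the calibrated analysis chain recovers
    ``cow_rate`` in expectation.
    """
    if cow_rate < 0:
        raise ValueError("cow_rate must be non-negative")
    if duration < 60:
        raise ValueError("duration must be at least 60 s")
    rng = child_rng(seed, "events", cow_id, session_id)
    if cow_rate == 0:
        times = np.empty(0)
        amps = np.empty(0)
    else:
        rate_per_s = params.eructation_rate / 60.0
        n_events = rng.poisson(rate_per_s * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n_events))
        mean_area = cow_rate / (params.station_gain * params.eructation_rate)
        sigma = np.sqrt(np.log1p(params.amplitude_cv**2))
        areas = mean_area * rng.lognormal(-(sigma**2) / 2.0, sigma, size=n_events)
        amps = areas / params.dilution_factor / params.pulse_unit_area
    return render_trace(times, amps, params, duration, seed, cow_id, session_id)


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CommunityParams:
    """Two-state rumen community model.

    ``base_proportions`` is the state-L composition on the simplex (indexed
    by OTU id); ``planted_effects`` maps OTU id to the H:L fold-change, so
    state H is the base with folds applied and renormalized.  Per cow-period,
    a composition is drawn Dirichlet(overdispersion * state proportions) and
    each of ``n_replicates`` libraries is multinomial at ``library_size``.
    """

    base_proportions: pd.Series
    taxonomy: pd.DataFrame  # index otu_id: lineage, domain, clade
    planted_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    archaea_fraction: float = 0.005
    clade_split: Mapping[str, tuple[float, float]] | None = None
    library_size: int = 40_000
    n_replicates: int = 3
    overdispersion: float = 2000.0

    def __post_init__(self) -> None:
        p = self.base_proportions
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("base_proportions must sum to 1")
        if (p < 0).any():
            raise ValueError("base_proportions must be non-negative")
        unknown = set(self.planted_effects) - set(p.index)
        if unknown:
            raise ValueError(f"planted effect for unknown OTU id(s): {sorted(unknown)}")
        if any(f <= 0 for f in self.planted_effects.values()):
            raise ValueError("fold-changes must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_otus(self) -> int:
        return len(self.base_proportions)

    def state_proportions(self, state: str) -> np.ndarray:
        """Composition of community state 'L' (base) or 'H' (folds applied)."""
        p = self.base_proportions.to_numpy(dtype=float).copy()
        if state == "H":
            for otu, fold in self.planted_effects.items():
                p[self.base_proportions.index.get_loc(otu)] *= fold
        elif state != "L":
            raise ValueError(f"unknown community state {state!r}")
        return p / p.sum()


# Differential OTUs planted by default: mean % relative abundance in the
# community state associated with low (L) and high (H) emission.
_DIFFERENTIAL_OTUS = [
    ("Succinivibrionaceae", "807342", 1.99, 0.44),
    ("Prevotella", "290504", 1.67, 0.09),
    ("Prevotella", "100265", 1.08, 0.44),
    ("Prevotella", "84373", 0.88, 0.57),
    ("Prevotella", "2115", 0.86, 0.68),
    ("Prevotella", "241137", 0.82, 0.46),
    ("Prevotella", "268683", 0.65, 0.26),
    ("Bacteroidales", "107308", 0.48, 0.33),
    ("Prevotella", "2093", 0.39, 0.30),
    ("Prevotella", "205082", 0.35, 0.26),
    ("Prevotella", "576319", 0.34, 0.24),
    ("Paraprevotellaceae", "143138", 0.29, 0.14),
    ("Ruminococcus", "270733", 0.28, 0.10),
    ("Prevotella", "86234", 0.89, 2.00),
    ("Prevotella", "579901", 1.30, 1.97),
    ("Prevotella", "267490", 0.68, 1.56),
    ("Succiniclasticum", "2230984", 0.88, 1.27),
    ("Prevotella", "69910", 0.26, 1.26),
    ("Prevotella", "2051", 0.67, 1.15),
    ("Prevotella", "539926", 0.53, 1.10),
    ("Fibrobacter", "262032", 0.52, 0.83),
    ("Prevotella", "2082", 0.46, 0.80),
    ("Prevotella", "263905", 0.34, 0.75),
    ("Prevotella", "169258", 0.41, 0.64),
    ("Bacteroidales", "572735", 0.22, 0.50),
    ("Bifidobacteriaceae", "551305", 0.01, 0.47),
]

_LINEAGES = {
    "Prevotella": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Prevotellaceae; g__Prevotella",
    "Succinivibrionaceae": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Aeromonadales; f__Succinivibrionaceae; g__",
    "Succiniclasticum": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Veillonellaceae; g__Succiniclasticum",
    "Fibrobacter": "k__Bacteria; p__Fibrobacteres; c__Fibrobacteria; o__Fibrobacterales; f__Fibrobacteraceae; g__Fibrobacter",
    "Ruminococcus": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Ruminococcaceae; g__Ruminococcus",
    "Bacteroidales": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__; g__",
    "Paraprevotellaceae": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Paraprevotellaceae; g__",
    "Bifidobacteriaceae": "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Bifidobacteriales; f__Bifidobacteriaceae; g__",
    "Lachnospiraceae": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__",
}

_ARCHAEA_BASE = "k__Archaea; p__Euryarchaeota; c__Methanobacteria; o__Methanobacteriales; f__Methanobacteriaceae; g__Methanobrevibacter"

# Archaeal composition (% of archaeal reads) per community state: the
# Methanobrevibacter ruminantium clade dominates state L, the gottschalkii
# clade rises in state H, plus Methanosphaera, Methanomassiliicoccaceae (more
# abundant in L) and a residual Methanobrevibacter share.
_ARCHAEA_SPLIT = {
    "L": {"ruminantium": 61.8, "gottschalkii": 25.4, "msp": 4.8, "mmc": 6.9, "other": 1.1},
    "H": {"ruminantium": 40.7, "gottschalkii": 44.0, "msp": 4.8, "mmc": 4.6, "other": 5.9},
}


def default_community_params(
    n_filler: int = 90,
    archaea_fraction: float = 0.005,
    library_size: int = 40_000,
    n_replicates: int = 3,
    overdispersion: float = 2000.0,
    seed: int = 0,
) -> CommunityParams:
    """Default two-state community with planted differential OTUs.

    Planted bacterial effects use the observed differential-OTU magnitudes
    (e.g. a Succinivibrionaceae OTU at 1.99 % of reads in state L vs 0.44 %
    in state H); archaeal OTUs carry clade labels with opposing
    ruminantium/gottschalkii abundance between states; the remaining mass is
    spread over ``n_filler`` undifferentiated OTUs with a geometric-decay
    profile.
    """
    ids: list[str] = []
    lineages: list[str] = []
    domains: list[str] = []
    clades: list[str] = []
    props: list[float] = []
    effects: dict[str, float] = {}

    for genus, ref, mean_l, mean_h in _DIFFERENTIAL_OTUS:
        otu = f"OTU_{ref}"
        ids.append(otu)
        lineages.append(f"{_LINEAGES[genus]}; x__{ref}")
        domains.append("bacteria")
        clades.append("")
        props.append(mean_l / 100.0)
        effects[otu] = mean_h / mean_l

    # archaea: two ruminantium-clade OTUs, two gottschalkii-clade OTUs,
    # Methanosphaera, Methanomassiliicoccaceae and a residual clade.
    arch = _ARCHAEA_SPLIT
    arch_otus = [
        ("OTU_A_rum1", f"{_ARCHAEA_BASE}; s__ruminantium_clade", "ruminantium", 0.7),
        ("OTU_A_rum2", f"{_ARCHAEA_BASE}; s__ruminantium_clade", "ruminantium", 0.3),
        ("OTU_A_got1", f"{_ARCHAEA_BASE}; s__gottschalkii_clade", "gottschalkii", 0.6),
        ("OTU_A_got2", f"{_ARCHAEA_BASE}; s__gottschalkii_clade", "gottschalkii", 0.4),
        (
            "OTU_A_msp",
            "k__Archaea; p__Euryarchaeota; c__Methanobacteria; o__Methanobacteriales; f__Methanobacteriaceae; g__Methanosphaera",
            "other",
            1.0,
        ),
        (
            "OTU_A_mmc",
            "k__Archaea; p__Euryarchaeota; c__Thermoplasmata; o__E2; f__Methanomassiliicoccaceae; g__",
            "other",
            1.0,
        ),
        ("OTU_A_mbb", f"{_ARCHAEA_BASE}; s__", "other", 1.0),
    ]
    share_key = {
        "OTU_A_rum1": "ruminantium",
        "OTU_A_rum2": "ruminantium",
        "OTU_A_got1": "gottschalkii",
        "OTU_A_got2": "gottschalkii",
        "OTU_A_msp": "msp",
        "OTU_A_mmc": "mmc",
        "OTU_A_mbb": "other",
    }
    for otu, lineage, clade, within in arch_otus:
        key = share_key[otu]
        p_l = archaea_fraction * arch["L"][key] / 100.0 * within
        p_h = archaea_fraction * arch["H"][key] / 100.0 * within
        ids.append(otu)
        lineages.append(lineage)
        domains.append("archaea")
        clades.append(clade)
        props.append(p_l)
        effects[otu] = p_h / p_l

    # filler bacteria: geometric decay, no planted effect
    remaining = 1.0 - sum(props)
    if remaining <= 0:
        raise ValueError("planted proportions exceed the simplex")
    decay = 0.96
    weights = decay ** np.arange(n_filler)
    weights = weights / weights.sum() * remaining
    filler_genera = ["Prevotella", "Lachnospiraceae", "Ruminococcus", "Bacteroidales"]
    for i in range(n_filler):
        genus = filler_genera[i % len(filler_genera)]
        otu = f"OTU_F{i + 1:03d}"
        ids.append(otu)
        lineages.append(f"{_LINEAGES[genus]}; x__F{i + 1:03d}")
        domains.append("bacteria")
        clades.append("")
        props.append(weights[i])

    base = pd.Series(props, index=ids, name="proportion")
    taxonomy = pd.DataFrame(
        {"lineage": lineages, "domain": domains, "clade": clades}, index=ids
    )
    taxonomy.index.name = "otu_id"
    return CommunityParams(
        base_proportions=base / base.sum(),
        taxonomy=taxonomy,
        planted_effects=effects,
        archaea_fraction=archaea_fraction,
        clade_split={
            "L": (arch["L"]["ruminantium"] / 100, arch["L"]["gottschalkii"] / 100),
            "H": (arch["H"]["ruminantium"] / 100, arch["H"]["gottschalkii"] / 100),
        },
        library_size=library_size,
        n_replicates=n_replicates,
        overdispersion=overdispersion,
    )


def gen_otu_table(cows: HerdConfig, params: CommunityParams, seed: int = 0) -> OtuTable:
    """Draw triplicate OTU libraries per cow and period.

    For each cow x period a composition is drawn Dirichlet(overdispersion *
    state proportions) around the cow's planted community state; each
    replicate library is a multinomial draw of ``library_size`` reads.
    """
    state_p = {s: params.state_proportions(s) for s in ("L", "H")}
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for cow in cows.cows:
        state = cows.cluster_assignment[cow]
        for period in cows.periods:
            rng = child_rng(seed, "otu", cow, period)
            alpha = params.overdispersion * state_p[state]
            q = rng.dirichlet(np.clip(alpha, 1e-8, None))
            for rep in range(1, params.n_replicates + 1):
                lib = f"{cow}_{period}_{rep}"
                cols[lib] = rng.multinomial(params.library_size, q)
                meta_rows.append((lib, cow, period, rep))
    counts = pd.DataFrame(cols, index=params.base_proportions.index)
    counts.index.name = "otu_id"
    samples = pd.DataFrame(
        meta_rows, columns=["library_id", "cow_id", "period", "replicate"]
    ).set_index("library_id")
    return OtuTable(counts=counts, samples=samples, taxonomy=params.taxonomy.copy())


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def default_qpcr_truth(
    groups: pd.Series, target: str = "RO", seed: int = 0, cv: float = 0.3
) -> pd.Series:
    """True copies/mL per cow for a target assay, drawn around emitter-group
    geometric means (RO declines from low to high emitters; SGMT does not)."""
    means = {
        "RO": {"L": 2.2e7, "M": 1.4e7, "H": 6.8e6},
        "SGMT": {"L": 2.5e7, "M": 1.9e7, "H": 2.7e7},
    }[target]
    rng = child_rng(seed, "qpcr-truth", target)
    sigma = np.sqrt(np.log1p(cv**2))
    vals = {
        cow: means[g] * rng.lognormal(-(sigma**2) / 2.0, sigma)
        for cow, g in groups.items()
    }
    return pd.Series(vals, name=f"true_copies_per_ml_{target}")


def gen_qpcr_data(
    true_copies_per_ml: Mapping[str, float] | pd.Series,
    curve: StandardCurve,
    dilutions: tuple[int, ...] = (50, 100),
    noise_sd: float = 0.2,
    seed: int = 0,
    target: str = "RO",
    n_replicates: int = 3,
    template_volume_ul: float = 3.0,
    periods: tuple = (1,),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a standard-curve point table and a sample Cq table.

    Standards span 10^0..10^8 plasmid copies with
    Cq = intercept + slope * log10(copies) + noise.  Sample Cq values are
    back-computed from each cow's true copies/mL through the stated dilution
    and template volume, so zero-noise quantification recovers the truth
    exactly.
    """
    if curve.slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    for d in dilutions:
        if d <= 0:
            raise ValueError("dilution factors must be positive")
    truth = pd.Series(true_copies_per_ml)
    if (truth <= 0).any():
        raise ValueError("true copies must be positive")

    rng = child_rng(seed, "qpcr", target)
    std_rows = []
    for level in range(9):  # 10^0 .. 10^8 copies
        copies = 10.0**level
        for rep in range(1, n_replicates + 1):
            cq = curve.intercept + curve.slope * level + noise_sd * rng.standard_normal()
            std_rows.append((f"std{level}_{rep}", target, "standard", copies, cq))
    standards = pd.DataFrame(
        std_rows, columns=["well", "target", "kind", "copies", "cq"]
    )

    sample_rows = []
    for cow, c_ml in truth.items():
        for period in periods:
            for dil in dilutions:
                copies_rxn = c_ml * template_volume_ul / (dil * 1000.0)
                for rep in range(1, n_replicates + 1):
                    cq = (
                        curve.intercept
                        + curve.slope * np.log10(copies_rxn)
                        + noise_sd * rng.standard_normal()
                    )
                    sample_rows.append(
                        (f"{cow}_p{period}_d{dil}_{rep}", target, "sample", cow, period, dil, cq)
                    )
    samples = pd.DataFrame(
        sample_rows,
        columns=["well", "target", "kind", "cow_id", "period", "dilution", "cq"],
    )
    return standards, samples


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

DEFAULT_DIGESTIBILITY = {"DM": 0.690, "OM": 0.710, "NDF": 0.640, "CP": 0.700}

#: Feed nutrient composition, g/kg DM (AIA is the indigestible marker).
DEFAULT_FEED_COMPOSITION = {"OM": 930.0, "NDF": 350.0, "CP": 175.0, "AIA": 10.0}

#: VFA molar proportions (mol/100 mol) per community state.
DEFAULT_VFA_STATE_MEANS = {
    "L": {
        "acetate": 61.1,
        "propionate": 19.6,
        "butyrate": 14.7,
        "i_butyrate": 0.77,
        "valerate": 3.07,
        "i_valerate": 0.51,
    },
    "H": {
        "acetate": 61.8,
        "propionate": 17.1,
        "butyrate": 17.3,
        "i_butyrate": 0.73,
        "valerate": 2.80,
        "i_valerate": 0.27,
    },
}

DEFAULT_MILK_PARAMS = {
    "milk_kg": (33.5, 2.5),
    "fat": (41.0, 1.5),  # g/kg
    "protein": (34.7, 1.2),
    "lactose": (47.6, 0.8),
}


@dataclasses.dataclass
class PhenotypeTables:
    """Generated intake, feces, milk and VFA tables plus planted truth."""

    intake: pd.DataFrame
    feces: pd.DataFrame
    milk: pd.DataFrame
    vfa: pd.DataFrame
    truth: dict


def gen_phenotype_tables(
    cows: HerdConfig,
    true_digestibility: Mapping[str, float] | None = None,
    vfa_state_means: Mapping[str, Mapping[str, float]] | None = None,
    milk_params: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    fecal_conc_rel_sd: float = 0.001,
    vfa_sd: float = 0.5,
    dmi_mean: float = 24.0,
    dmi_sd: float = 1.5,
    feed_composition: Mapping[str, float] | None = None,
) -> PhenotypeTables:
    """Generate feed-intake, fecal-composition, milk and VFA tables.

    Fecal nutrient masses follow from intake and the true digestibilities;
    the acid-insoluble-ash (AIA) marker is fully recovered by construction
    (AIA excreted equals AIA ingested), so marker-based digestibility
    round-trips the truth exactly at zero measurement noise.
    ``fecal_conc_rel_sd`` is the relative SD of the reported fecal
    concentrations (composite-sample analytical precision).
    """
    dig = dict(DEFAULT_DIGESTIBILITY if true_digestibility is None else true_digestibility)
    for nutrient, d in dig.items():
        if not 0.0 < d < 1.0:
            raise ValueError(f"digestibility of {nutrient} must be in (0, 1)")
    comp = dict(DEFAULT_FEED_COMPOSITION if feed_composition is None else feed_composition)
    vfa_means = dict(DEFAULT_VFA_STATE_MEANS if vfa_state_means is None else vfa_state_means)
    for state, acids in vfa_means.items():
        total = sum(acids.values())
        if abs(total - 100.0) > 1.0:
            raise ValueError(
                f"VFA proportions for state {state!r} must sum to ~100 mol/100 mol, got {total:.2f}"
            )
    milk_p = dict(DEFAULT_MILK_PARAMS if milk_params is None else milk_params)

    intake_rows, feces_rows, milk_rows, vfa_rows, fecal_dm_rows = [], [], [], [], []
    for cow in cows.cows:
        state = cows.cluster_assignment[cow]
        for period in cows.periods:
            rng = child_rng(seed, "pheno", cow, period)
            dmi = max(dmi_mean + dmi_sd * rng.standard_normal(), 1.0)
            intake_rows.append((cow, period, dmi, *[comp[k] for k in ("OM", "NDF", "CP", "AIA")]))

            fecal_dm = dmi * (1.0 - dig["DM"])  # kg/day, from DM digestibility
            conc = {}
            for nutrient in ("OM", "NDF", "CP"):
                mass_in = dmi * comp[nutrient] / 1000.0
                mass_out = mass_in * (1.0 - dig[nutrient])
                conc[nutrient] = mass_out / fecal_dm * 1000.0
            aia_in = dmi * comp["AIA"] / 1000.0
            conc["AIA"] = aia_in / fecal_dm * 1000.0  # full marker recovery
            noise = 1.0 + fecal_conc_rel_sd * rng.standard_normal(4)
            feces_rows.append(
                (cow, period, *(conc[k] * e for k, e in zip(("OM", "NDF", "CP", "AIA"), noise)))
            )
            fecal_dm_rows.append((cow, period, fecal_dm))

            mk = {k: m + s * rng.standard_normal() for k, (m, s) in milk_p.items()}
            milk_rows.append((cow, period, mk["milk_kg"], mk["fat"], mk["protein"], mk["lactose"]))

            acids = vfa_means[state]
            draws = {}
            for acid, mean in acids.items():
                sd = vfa_sd if mean > 5 else vfa_sd / 5.0
                draws[acid] = max(mean + sd * rng.standard_normal(), 0.01)
            total = sum(draws.values())
            vfa_rows.append((cow, period, *(v * 100.0 / total for v in draws.values())))

    acid_names = list(next(iter(vfa_means.values())).keys())
    intake = pd.DataFrame(
        intake_rows,
        columns=["cow_id", "period", "dmi_kg", "OM_g_per_kg", "NDF_g_per_kg", "CP_g_per_kg", "AIA_g_per_kg"],
    )
    feces = pd.DataFrame(
        feces_rows,
        columns=["cow_id", "period", "OM_g_per_kg", "NDF_g_per_kg", "CP_g_per_kg", "AIA_g_per_kg"],
    )
    milk = pd.DataFrame(
        milk_rows, columns=["cow_id", "period", "milk_kg", "fat", "protein", "lactose"]
    )
    vfa = pd.DataFrame(vfa_rows, columns=["cow_id", "period", *acid_names])
    fecal_dm = pd.DataFrame(fecal_dm_rows, columns=["cow_id", "period", "fecal_dm_kg"])
    truth = {
        "digestibility": dig,
        "fecal_dm": fecal_dm,
        "state": cows.cluster_assignment.copy(),
        "vfa_state_means": vfa_means,
    }
    return PhenotypeTables(intake=intake, feces=feces, milk=milk, vfa=vfa, truth=truth)
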