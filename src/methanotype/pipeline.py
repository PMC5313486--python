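"""End-to-end orchestration: sniffer -> phenotype -> qPCR -> community.

A single :class:`RunConfig` drives either a fully simulated study (the
``simulate`` block) or analysis of on-disk inputs (the ``inputs`` block).
The run produces a :class:`StudyReport` bundling the group-level phenotype
table, the community-cluster table, the differential-OTU table, ordination
coordinates and a provenance block (config hash, seed, versions).  Every
filtered entity (discarded peak, removed milking, dropped OTU or library)
is logged with the rule that removed it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.vq import kmeans2

from . import __version__, community, io, phenotype, qpcr, simulate, sniffer
from ._rng import child_rng

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyReport", "validate_config", "run_pipeline"]

_THRESHOLD_DEFAULTS = {
    "min_height": 200.0,  # mg/kg above baseline
    "min_peaks": 3,
    "window_days": 14,
    "min_fraction": 0.001,  # univariate differential-abundance threshold
    "detect_fraction": 1e-5,  # OTU-table read-count filter
    "n_perm": 999,
    "alpha": 0.05,
    "fdr_q": 0.05,
    "subsample_depth": "min",
}

_SIMULATE_DEFAULTS = {
    "n_cows": 21,
    "n_periods": 3,
    "sessions_per_day": 2.5,
    "period_days": 14,
    "session_duration_s": 480.0,
    "library_size": 40_000,
    "overdispersion": 2000.0,
    "n_filler_otus": 90,
}

_INPUT_KEYS = {
    "gas_log",
    "calibration",
    "otu_counts",
    "otu_taxonomy",
    "otu_samples",
    "qpcr",
    "intake",
    "feces",
    "milk",
    "vfa",
}


class ConfigError(ValueError):
    """Aggregated, human-readable configuration errors."""


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str | None = None
    simulate: dict | None = None
    inputs: dict | None = None
    thresholds: dict = dataclasses.field(default_factory=dict)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(cfg: dict) -> RunConfig:
    """Normalise a raw config dict: fill defaults, reject unknown keys.

    Exactly one of the ``simulate`` and ``inputs`` blocks must be present.
    All errors are aggregated into one message.
    """
    errors: list[str] = []
    known_top = {"seed", "outdir", "simulate", "inputs", "thresholds"}
    for key in set(cfg) - known_top:
        errors.append(f"unknown config key: {key!r}")

    has_sim = "simulate" in cfg and cfg["simulate"] is not None
    has_inp = "inputs" in cfg and cfg["inputs"] is not None
    if has_sim == has_inp:
        errors.append("exactly one of 'simulate' and 'inputs' must be present")

    thresholds = dict(_THRESHOLD_DEFAULTS)
    for key, val in (cfg.get("thresholds") or {}).items():
        if key not in _THRESHOLD_DEFAULTS:
            errors.append(f"unknown threshold: {key!r}")
            continue
        thresholds[key] = val
    for key in ("min_height", "min_peaks", "window_days", "n_perm"):
        if not isinstance(thresholds[key], str) and thresholds[key] <= 0:
            errors.append(f"threshold {key!r} must be positive")
    if not 0 < thresholds["min_fraction"] < 1:
        errors.append("threshold 'min_fraction' must be in (0, 1)")

    sim = None
    if has_sim:
        sim = dict(_SIMULATE_DEFAULTS)
        for key, val in (cfg["simulate"] or {}).items():
            if key not in _SIMULATE_DEFAULTS:
                errors.append(f"unknown simulate key: {key!r}")
                continue
            sim[key] = val
    inputs = None
    if has_inp:
        inputs = dict(cfg["inputs"])
        for key in set(inputs) - _INPUT_KEYS:
            errors.append(f"unknown inputs key: {key!r}")

    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(
        seed=int(cfg.get("seed", 0)),
        outdir=cfg.get("outdir"),
        simulate=sim,
        inputs=inputs,
        thresholds=thresholds,
    )


@dataclasses.dataclass
class StudyReport:
    """Machine-readable study report with full provenance."""

    emitter_groups: pd.Series
    period_emissions: pd.DataFrame  # cow x period mean rates
    group_table: pd.DataFrame  # phenotype means by emitter group (+ SED)
    cluster_table: pd.DataFrame  # phenotype means by community cluster
    cluster_labels: pd.Series  # per cow
    qpcr_table: pd.DataFrame
    ordination: community.OrdinationResult
    permanova: community.PermanovaResult
    differential: pd.DataFrame
    clade_ratios: pd.Series
    provenance: dict

    def summary(self) -> dict:
        counts = self.emitter_groups.value_counts().to_dict()
        return {
            "provenance": self.provenance,
            "emitter_group_counts": {str(k): int(v) for k, v in counts.items()},
            "permanova": {
                "pseudo_F": self.permanova.statistic,
                "p_value": self.permanova.p_value,
                "n_permutations": self.permanova.n_permutations,
            },
            "pco_explained_pct": [float(x) for x in self.ordination.explained_pct[:2]],
            "n_differential_otus_q05": int((self.differential["q"] < 0.05).sum())
            if len(self.differential)
            else 0,
            "clade_ratio_by_group": {
                str(k): float(v) for k, v in self.clade_ratios.items()
            },
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.period_emissions.to_csv(out / "period_emissions.csv")
        self.emitter_groups.to_csv(out / "emitter_groups.csv")
        self.group_table.to_csv(out / "group_table.csv")
        self.cluster_table.to_csv(out / "cluster_table.csv")
        self.cluster_labels.to_csv(out / "cluster_labels.csv")
        self.qpcr_table.to_csv(out / "qpcr_copies_per_ml.csv", index=False)
        self.ordination.coordinates.to_csv(out / "pcoa_coordinates.csv")
        self.differential.to_csv(out / "differential_otus.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary(), indent=2, sort_keys=True))


def _simulate_sessions(herd, trace_params, cfg) -> pd.DataFrame:
    """Simulate and analyse every milking session of the study."""
    cal = sniffer.calibrate_dilution(
        [("base", 10_000.0, 10_000.0 / trace_params.dilution_factor)] * 5
        + [("center", 10_000.0, 10_000.0 / trace_params.dilution_factor)] * 5,
        station_gain=trace_params.station_gain,
    )
    thresholds = cfg.thresholds
    sim = cfg.simulate
    n_sessions = int(round(sim["sessions_per_day"] * sim["period_days"]))
    rows = []
    for cow in herd.cows:
        rate = float(herd.true_rates[cow])
        for period in herd.periods:
            for s in range(n_sessions):
                day = (period - 1) * sim["period_days"] + s / sim["sessions_per_day"]
                session_id = f"{cow}_p{period}_s{s}"
                trace = simulate.gen_gas_trace(
                    rate,
                    trace_params,
                    duration=sim["session_duration_s"],
                    seed=cfg.seed,
                    cow_id=cow,
                    session_id=session_id,
                )
                baseline = sniffer.estimate_baseline(trace)
                peaks = sniffer.detect_peaks(
                    trace, baseline, min_height=thresholds["min_height"]
                )
                summ = sniffer.summarize_milking(
                    peaks,
                    trace.duration_min,
                    min_peaks=thresholds["min_peaks"],
                    cow_id=cow,
                    session_id=session_id,
                )
                rate_est = sniffer.index_to_rate(summ, cal) if summ.valid else np.nan
                if not summ.valid:
                    logger.info(
                        "session %s removed: %d peaks < %d",
                        session_id,
                        summ.n_peaks,
                        thresholds["min_peaks"],
                    )
                rows.append((cow, day, period, rate_est))
    return pd.DataFrame(rows, columns=["cow_id", "day", "period", "rate"])


def _phenotype_tables(values: pd.DataFrame, by: pd.Series, name: str) -> pd.DataFrame:
    """Mean of each numeric column per group plus the largest pairwise SED."""
    df = values.copy()
    df[name] = by.reindex(df.index).to_numpy()
    grouped = df.groupby(name)
    means = grouped.mean()
    sed_rows = {}
    for col in values.columns:
        seds = []
        stats = grouped[col].agg(["var", "count"])
        for i, a in enumerate(stats.index):
            for b in stats.index[i + 1 :]:
                va, na = stats.loc[a, "var"], stats.loc[a, "count"]
                vb, nb = stats.loc[b, "var"], stats.loc[b, "count"]
                if na > 1 and nb > 1:
                    seds.append(np.sqrt(va / na + vb / nb))
        sed_rows[col] = max(seds) if seds else np.nan
    out = means.T
    out["SED"] = pd.Series(sed_rows)
    return out


def run_pipeline(config: RunConfig | dict) -> StudyReport:
    """Execute the full chain and return a :class:`StudyReport`.

    Simulated mode generates all inputs from the planted herd first; input
    mode reads them from disk.  Deterministic for a fixed seed.
    """
    cfg = validate_config(config) if isinstance(config, dict) else config
    seed = cfg.seed

    if cfg.simulate is not None:
        sim = cfg.simulate
        herd = simulate.make_herd(
            n_cows=sim["n_cows"],
            n_periods=sim["n_periods"],
            seed=seed,
            sessions_per_day=sim["sessions_per_day"],
            period_days=sim["period_days"],
        )
        trace_params = simulate.TraceParams()
        sessions = _simulate_sessions(herd, trace_params, cfg)
        periods = {
            p: ((p - 1) * sim["period_days"], p * sim["period_days"])
            for p in herd.periods
        }
        pheno = simulate.gen_phenotype_tables(herd, seed=seed)
        intake, feces, milk, vfa = pheno.intake, pheno.feces, pheno.milk, pheno.vfa

        cparams = simulate.default_community_params(
            n_filler=sim["n_filler_otus"],
            library_size=sim["library_size"],
            overdispersion=sim["overdispersion"],
        )
        otu_table = simulate.gen_otu_table(herd, cparams, seed=seed)

        true_curves = {
            "RO": qpcr.StandardCurve(slope=-3.46, intercept=38.0, r2=0.999),
            "SGMT": qpcr.StandardCurve(slope=-3.53, intercept=37.5, r2=0.987),
        }
        qpcr_frames = []
        for target, curve in true_curves.items():
            truth = simulate.default_qpcr_truth(
                herd.true_groups, target=target, seed=seed
            )
            standards, samples = simulate.gen_qpcr_data(
                truth, curve, seed=seed, target=target, periods=tuple(herd.periods)
            )
            fitted = qpcr.fit_standard_curve(
                list(zip(standards["copies"], standards["cq"]))
            )
            qpcr_frames.append(qpcr.quantify_samples(samples, fitted))
        qpcr_table = pd.concat(qpcr_frames, ignore_index=True)
    else:
        inp = cfg.inputs
        traces = io.read_gas_log(inp["gas_log"])
        cal_df = pd.read_csv(inp["calibration"])
        cal = sniffer.calibrate_dilution(
            list(cal_df[["site", "released", "sampled"]].itertuples(index=False))
        )
        rows = []
        for trace in traces:
            baseline = sniffer.estimate_baseline(trace)
            peaks = sniffer.detect_peaks(
                trace, baseline, min_height=cfg.thresholds["min_height"]
            )
            summ = sniffer.summarize_milking(
                peaks,
                trace.duration_min,
                min_peaks=cfg.thresholds["min_peaks"],
                cow_id=trace.cow_id,
                session_id=trace.session_id,
            )
            rate_est = sniffer.index_to_rate(summ, cal) if summ.valid else np.nan
            day = float(str(trace.session_id).rsplit("d", 1)[-1]) if "d" in str(trace.session_id) else 0.0
            rows.append((trace.cow_id, day, rate_est))
        sessions = pd.DataFrame(rows, columns=["cow_id", "day", "rate"])
        periods = None
        intake = pd.read_csv(inp["intake"])
        feces = pd.read_csv(inp["feces"])
        milk = pd.read_csv(inp["milk"])
        vfa = pd.read_csv(inp["vfa"])
        otu_table = io.read_otu_table(
            inp["otu_counts"], inp["otu_taxonomy"], inp["otu_samples"]
        )
        standards, samples = io.read_qpcr(inp["qpcr"])
        qpcr_frames = []
        for target, sub in standards.groupby("target"):
            fitted = qpcr.fit_standard_curve(list(zip(sub["copies"], sub["cq"])))
            qpcr_frames.append(
                qpcr.quantify_samples(samples[samples["target"] == target], fitted)
            )
        qpcr_table = pd.concat(qpcr_frames, ignore_index=True)

    # ----- emissions and emitter groups -----
    session_rates = sessions[["cow_id", "day", "rate"]]
    emissions = sniffer.period_average(
        session_rates, window_days=cfg.thresholds["window_days"], periods=periods
    )
    emission_matrix = sniffer.period_emission_matrix(emissions)
    groups = phenotype.classify_emitters(emission_matrix)

    # ----- phenotype summaries -----
    milk = milk.copy()
    milk["ecm_kg"] = phenotype.compute_ecm(
        milk["milk_kg"], milk["fat"], milk["protein"], milk["lactose"]
    )
    dig = phenotype.digestibility_table(intake, feces)
    mean_rate = emission_matrix.mean(axis=1)

    per_cow = (
        milk.groupby("cow_id")[["milk_kg", "ecm_kg"]]
        .mean()
        .join(intake.groupby("cow_id")["dmi_kg"].mean())
        .join(dig.groupby("cow_id")[["DM", "OM", "NDF", "CP"]].mean())
        .join(vfa.groupby("cow_id").mean(numeric_only=True).drop(columns="period"))
    )
    per_cow["ch4_g_per_day"] = mean_rate
    per_cow["ch4_per_kg_dmi"] = per_cow["ch4_g_per_day"] / per_cow["dmi_kg"]
    per_cow["ch4_per_kg_ecm"] = per_cow["ch4_g_per_day"] / per_cow["ecm_kg"]
    per_cow["ratio_abp"] = (per_cow["acetate"] + per_cow["butyrate"]) / per_cow[
        "propionate"
    ]
    group_table = _phenotype_tables(per_cow, groups, "emitter_group")

    # ----- community chain -----
    filtered = community.filter_replicate_consistency(otu_table)
    filtered = community.filter_min_reads(filtered, cfg.thresholds["detect_fraction"])
    depth = cfg.thresholds["subsample_depth"]
    filtered = community.subsample_even_depth(
        filtered, depth=None if depth == "min" else int(depth), seed=seed
    )
    bacterial_rel = community.relative_abundance(filtered, level="otu", domain="bacteria")
    dm = community.bray_curtis(bacterial_rel)
    ordination = community.pcoa(dm)

    coords = ordination.coordinates.iloc[:, : min(2, ordination.coordinates.shape[1])]
    rng = child_rng(seed, "cluster")
    _, assignments = kmeans2(
        coords.to_numpy(), 2, minit="++", seed=rng, iter=50
    )
    sample_cows = [sid.split("|")[0] for sid in coords.index]
    votes = pd.DataFrame({"cow_id": sample_cows, "k": assignments})
    cow_k = votes.groupby("cow_id")["k"].agg(lambda s: int(round(s.mean())))
    # orient: the cluster with the lower mean estimated emission is 'L'
    rate_by_k = mean_rate.reindex(cow_k.index).groupby(cow_k).mean()
    low_k = int(rate_by_k.idxmin())
    cluster_labels = cow_k.map(lambda k: "L" if k == low_k else "H").rename("cluster")

    sample_clusters = pd.Series(
        [cluster_labels.get(c, "L") for c in sample_cows], index=list(dm.ids)
    )
    perma = community.permanova(
        dm,
        sample_clusters,
        n_permutations=int(cfg.thresholds["n_perm"]),
        seed=seed,
        permute_unit=pd.Series(sample_cows, index=list(dm.ids)),
    )
    differential = community.differential_otus(
        bacterial_rel,
        cluster_labels,
        min_fraction=cfg.thresholds["min_fraction"],
        taxonomy=filtered.taxonomy,
    )

    clade_rel = community.relative_abundance(filtered, level="otu", domain="archaea")
    clade_cols = filtered.taxonomy.loc[clade_rel.columns, "clade"]
    clade_shares = clade_rel.T.groupby(clade_cols).sum().T
    sample_groups = pd.Series(
        [groups.get(c, "excluded") for c, _ in clade_shares.index],
        index=clade_shares.index,
    )
    _, clade_by_group = community.clade_ratio(clade_shares, groups=sample_groups)

    cluster_table = _phenotype_tables(per_cow, cluster_labels, "cluster")

    report = StudyReport(
        emitter_groups=groups,
        period_emissions=emission_matrix,
        group_table=group_table,
        cluster_table=cluster_table,
        cluster_labels=cluster_labels,
        qpcr_table=qpcr_table,
        ordination=ordination,
        permanova=perma,
        differential=differential,
        clade_ratios=clade_by_group.drop(index="excluded", errors="ignore"),
        provenance={
            "config_hash": cfg.config_hash(),
            "seed": seed,
            "package": "methanotype",
            "version": __version__,
        },
    )
    if cfg.outdir:
        report.write(cfg.outdir)
    return report
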