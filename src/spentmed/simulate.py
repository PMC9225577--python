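"""Seeded synthetic spent-medium experiments with known ground truth.

The generator emulates the experimental design behind the pipeline: a
defined medium whose tracked metabolites start at equal (equimolar)
amounts, isolates with archetype-structured consumption profiles
(generalists deplete many substrates strongly, specialists few), secretion
of novel features, logistic growth whose carrying capacity is linear in
total substrate consumed, re-culture of each recipient in each
influencer's spent medium, and MicroResp-style respiration readings.

Peak heights follow a multiplicative log-normal noise model around
analyte-specific baselines spanning roughly two orders of magnitude;
replicate structure, early/late medium controls and extraction blanks
mirror the triplicate layout the pipeline expects.  Everything is
deterministic given a seed, and at zero noise every stage of the pipeline
recovers the planted truth exactly.

The growth model is deliberately simple -- yield linear in consumed
substrate, no kinetics, no interaction beyond resource removal and
secretion -- a stand-in for real organisms, not a claim about them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GrowthTable,
    PeakHeightTable,
    SampleMetadata,
    write_growth_table,
    write_matrix,
)

#: fraction of a consumable secreted feature the recipient removes
SECRETION_CONSUMED_FRACTION = 0.9
#: A570 drop per unit substrate respired (indicator-gel sensitivity)
RESPIRATION_SCALE = 0.02
#: abiotic A570 drift of uninoculated controls over the incubation
CONTROL_A570_DRIFT = 0.02
#: flat OD reading of uninoculated medium wells
BLANK_OD = 0.005


@dataclass
class NoiseModel:
    """Multiplicative log-normal replicate noise and baseline structure.

    ``cv`` is the coefficient of variation of replicate peak heights; the
    log-normal factors are mean-one so expectations are unbiased.  Baseline
    peak heights are log-normal across analytes with ln-scale spread
    ``baseline_sigma`` (1.15 spans ~2 orders of magnitude at 2 sd).
    ``noise_floor`` is the background level seen in extraction blanks.
    """

    cv: float = 0.1
    n_replicates: int = 3
    baseline_median: float = 1e5
    baseline_sigma: float = 1.15
    noise_floor: float = 50.0
    seed: int = 0

    def factors(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic community.

    consumption[i, m] is the fraction of metabolite m isolate i removes
    from fresh medium; secretion[i, f] the peak amount of feature f it
    releases; consumability[i, f] whether isolate i can consume secreted
    feature f.  Yields are OD per unit substrate consumed (each medium
    metabolite contributes one unit when fully depleted).
    """

    consumption: pd.DataFrame  # isolates x metabolites, in [0, 1]
    secretion: pd.DataFrame  # isolates x secreted features, peak units
    consumability: pd.DataFrame  # isolates x secreted features, bool
    yield_coef: pd.Series  # OD per substrate unit
    respiration_frac: pd.Series  # fraction of consumed C respired
    growth_rate: pd.Series  # logistic r, 1/h
    groups: pd.Series  # "generalist" | "specialist"
    n0: float = 0.01
    #: fraction of a consumable secreted feature the recipient removes
    secretion_consumed_fraction: float = SECRETION_CONSUMED_FRACTION

    @property
    def isolates(self) -> list[str]:
        return list(self.consumption.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.consumption.columns)

    @property
    def secreted_features(self) -> list[str]:
        return list(self.secretion.columns)

    def substrate_units(self, baseline_median: float) -> pd.DataFrame:
        """Secretion amounts converted to medium-substrate units."""
        return self.secretion / baseline_median

    def consumed_in_fresh(self) -> pd.Series:
        return self.consumption.sum(axis=1)

    def consumed_in_spent(self, recipient: str, influencer: str,
                          baseline_median: float) -> float:
        """Substrate units a recipient obtains from an influencer's spent
        medium: residual metabolites plus consumable secretions."""
        c_r = self.consumption.loc[recipient]
        c_i = self.consumption.loc[influencer]
        residual = float((c_r * (1.0 - c_i)).sum())
        if self.secretion.shape[1]:
            s = self.substrate_units(baseline_median).loc[influencer]
            can = self.consumability.loc[recipient]
            residual += float(
                self.secretion_consumed_fraction * (s * can).sum()
            )
        return residual

    def expected_mis(self, baseline_median: float = 1e5) -> pd.DataFrame:
        """Ground-truth interaction strengths, recipients x influencers."""
        isolates = self.isolates
        out = pd.DataFrame(np.nan, index=isolates, columns=isolates)
        fresh = self.consumed_in_fresh()
        for r in isolates:
            for i in isolates:
                if r == i or fresh[r] == 0:
                    continue
                out.loc[r, i] = (
                    self.consumed_in_spent(r, i, baseline_median) / fresh[r] - 1.0
                )
        return out


def generate_truth(
    n_isolates: int = 8,
    n_metabolites: int = 60,
    seed: int = 0,
    generalist_support: int | None = None,
    specialist_support: int | None = None,
    n_secreted_per_isolate: int = 6,
    consumability_prob: float = 0.3,
    secretion_scale: float = 1e5,
    secretion_sigma: float = 0.5,
    secretion_consumed_fraction: float = SECRETION_CONSUMED_FRACTION,
) -> SyntheticTruth:
    """Draw a reproducible community truth with generalist/specialist
    archetypes.

    Half the isolates are generalists (large support, strong depletion,
    fast growth), half specialists.  ``n_secreted_per_isolate = 0`` gives a
    pure-competition community with no cross-feeding channel.
    """
    if n_isolates < 2 or n_metabolites < 2:
        raise ValueError("need >=2 isolates and >=2 metabolites")
    # defaults keep the 40/10 generalist/specialist contrast of the
    # reference 60-metabolite panel, scaled to the panel in use
    if generalist_support is None:
        generalist_support = max(2, round(n_metabolites * 2 / 3))
    if specialist_support is None:
        specialist_support = max(1, round(n_metabolites / 6))
    if max(generalist_support, specialist_support) > n_metabolites:
        raise ValueError("support size exceeds number of metabolites")
    rng = np.random.default_rng(seed)
    isolates = [f"iso{k + 1:02d}" for k in range(n_isolates)]
    metabolites = [f"met{m + 1:03d}" for m in range(n_metabolites)]
    n_gen = n_isolates // 2
    groups = pd.Series(
        ["generalist"] * n_gen + ["specialist"] * (n_isolates - n_gen),
        index=isolates,
    )

    C = pd.DataFrame(0.0, index=isolates, columns=metabolites)
    for iso in isolates:
        if groups[iso] == "generalist":
            support = rng.choice(n_metabolites, size=generalist_support, replace=False)
            fractions = rng.uniform(0.3, 1.0, size=generalist_support)
        else:
            support = rng.choice(n_metabolites, size=specialist_support, replace=False)
            fractions = rng.uniform(0.1, 0.7, size=specialist_support)
        C.iloc[C.index.get_loc(iso), support] = fractions

    sec_ids: list[str] = []
    sec_amounts: dict[str, dict[str, float]] = {iso: {} for iso in isolates}
    for iso in isolates:
        for k in range(n_secreted_per_isolate):
            fid = f"sec_{iso}_{k + 1}"
            sec_ids.append(fid)
            sec_amounts[iso][fid] = float(
                secretion_scale * rng.lognormal(0.0, secretion_sigma)
            )
    S = pd.DataFrame(0.0, index=isolates, columns=sec_ids)
    for iso in isolates:
        for fid, amt in sec_amounts[iso].items():
            S.loc[iso, fid] = amt
    can = pd.DataFrame(False, index=isolates, columns=sec_ids)
    for fid in sec_ids:
        producer = fid.split("_")[1]
        for iso in isolates:
            if iso != producer and rng.random() < consumability_prob:
                can.loc[iso, fid] = True

    is_gen = (groups == "generalist").to_numpy()
    yield_coef = pd.Series(rng.uniform(0.010, 0.030, n_isolates), index=isolates)
    growth_rate = pd.Series(
        np.where(is_gen, rng.uniform(0.4, 0.7, n_isolates),
                 rng.uniform(0.15, 0.35, n_isolates)),
        index=isolates,
    )
    respiration_frac = pd.Series(rng.uniform(0.2, 0.5, n_isolates), index=isolates)
    return SyntheticTruth(
        consumption=C,
        secretion=S,
        consumability=can,
        yield_coef=yield_coef,
        respiration_frac=respiration_frac,
        growth_rate=growth_rate,
        groups=groups,
        secretion_consumed_fraction=secretion_consumed_fraction,
    )


def _logistic_series(t: np.ndarray, K: float, N0: float, r: float) -> np.ndarray:
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def _meta_row(sample_id, isolate=None, role="spent", influencer=None,
              recipient=None, replicate=1, mode="positive", group=None) -> dict:
    return {
        "sample_id": sample_id,
        "isolate_id": isolate,
        "role": role,
        "influencer_id": influencer,
        "recipient_id": recipient,
        "replicate": replicate,
        "ionization_mode": mode,
        "control_group": group,
    }


@dataclass
class MonocultureExperiment:
    peaks: PeakHeightTable  # all analytes (metabolites + secreted features)
    metadata: SampleMetadata
    growth: GrowthTable
    baselines: pd.Series
    truth: SyntheticTruth

    def targeted_table(self) -> PeakHeightTable:
        """Medium metabolites only, as the targeted pipeline sees them."""
        sub = self.peaks.heights.loc[self.truth.metabolites]
        return PeakHeightTable(sub, table_kind="targeted")


def simulate_monocultures(
    truth: SyntheticTruth, noise: NoiseModel
) -> MonocultureExperiment:
    """Spent-medium peak table, metadata and growth curves for every isolate.

    Fast growers (generalists) are matched to the early medium control,
    slow growers (specialists) to the late one, mirroring the sampling of
    each isolate at its own early stationary phase.
    """
    rng = np.random.default_rng(noise.seed)
    n = noise.n_replicates
    metabolites = truth.metabolites
    analytes = metabolites + truth.secreted_features
    baselines = pd.Series(
        noise.baseline_median
        * np.exp(rng.normal(0.0, noise.baseline_sigma, len(metabolites))),
        index=metabolites,
    )
    base_all = pd.concat(
        [baselines, pd.Series(0.0, index=truth.secreted_features)]
    )

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    def add_sample(sample_id: str, expectation: np.ndarray, **meta) -> None:
        columns[sample_id] = expectation * noise.factors(rng, len(analytes))
        meta_rows.append(_meta_row(sample_id, **meta))

    floor = np.full(len(analytes), noise.noise_floor)
    medium_exp = np.maximum(base_all.to_numpy(), noise.noise_floor)

    for k in range(1, n + 1):
        add_sample(f"ctrl_early_{k}", medium_exp, role="medium_control_early",
                   replicate=k, group="early")
        add_sample(f"ctrl_late_{k}", medium_exp, role="medium_control_late",
                   replicate=k, group="late")
        add_sample(f"blank_{k}", floor, role="extraction_control", replicate=k)

    for iso in truth.isolates:
        group = "early" if truth.groups[iso] == "generalist" else "late"
        exp = medium_exp.copy()
        c = truth.consumption.loc[iso].to_numpy()
        exp[: len(metabolites)] = baselines.to_numpy() * (1.0 - c)
        for f in truth.secreted_features:
            j = analytes.index(f)
            exp[j] = noise.noise_floor + truth.secretion.loc[iso, f]
        for k in range(1, n + 1):
            add_sample(f"{iso}_spent_{k}", exp, isolate=iso, role="spent",
                       replicate=k, group=group)

    peaks = PeakHeightTable(
        pd.DataFrame(columns, index=analytes), table_kind="untargeted"
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    t = np.arange(0.0, 48.0 + 1e-9, 0.5)
    od_rows = []
    for iso in truth.isolates:
        K = truth.n0 + truth.yield_coef[iso] * truth.consumed_in_fresh()[iso]
        series = _logistic_series(t, K, truth.n0, truth.growth_rate[iso])
        for k in range(1, n + 1):
            od = series * noise.factors(rng, len(t))
            od_rows.append(
                pd.DataFrame(
                    {"isolate": iso, "medium": "SDM", "replicate": k,
                     "time_h": t, "od600": od}
                )
            )
    for k in range(1, n + 1):
        od = BLANK_OD * noise.factors(rng, len(t))
        od_rows.append(
            pd.DataFrame(
                {"isolate": "", "medium": "SDM", "replicate": k,
                 "time_h": t, "od600": od}
            )
        )
    growth = GrowthTable(pd.concat(od_rows, ignore_index=True))
    return MonocultureExperiment(peaks, meta, growth, baselines, truth)


@dataclass
class SequentialExperiment:
    peaks: PeakHeightTable
    metadata: SampleMetadata
    growth: GrowthTable  # recipient OD series + respiration readings
    true_mis: pd.DataFrame  # recipients x influencers


def simulate_sequential(
    mono: MonocultureExperiment,
    noise: NoiseModel,
    pairs: list[tuple[str, str]] | None = None,
    time_step_h: float = 0.5,
) -> SequentialExperiment:
    """Sequential growth of each recipient in each influencer's spent medium.

    Produces double-spent peak tables (with abiotic spent controls),
    recipient growth curves in every spent medium and in fresh medium, and
    MicroResp absorbance pairs, alongside the ground-truth interaction
    matrix implied by the community's consumption/secretion structure.
    """
    truth = mono.truth
    rng = np.random.default_rng(noise.seed + 1)
    n = noise.n_replicates
    metabolites = truth.metabolites
    analytes = metabolites + truth.secreted_features
    baselines = mono.baselines
    if pairs is None:
        pairs = [
            (r, i) for r in truth.isolates for i in truth.isolates if r != i
        ]

    def spent_expectation(iso: str) -> np.ndarray:
        exp = np.maximum(baselines.to_numpy(), noise.noise_floor) * (
            1.0 - truth.consumption.loc[iso].to_numpy()
        )
        sec = np.full(len(truth.secreted_features), noise.noise_floor)
        for j, f in enumerate(truth.secreted_features):
            sec[j] += truth.secretion.loc[iso, f]
        return np.concatenate([exp, sec])

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    def add_sample(sample_id: str, expectation: np.ndarray, **meta) -> None:
        columns[sample_id] = expectation * noise.factors(rng, len(analytes))
        meta_rows.append(_meta_row(sample_id, **meta))

    floor = np.full(len(analytes), noise.noise_floor)
    medium_exp = np.maximum(
        pd.concat(
            [baselines, pd.Series(0.0, index=truth.secreted_features)]
        ).to_numpy(),
        noise.noise_floor,
    )
    for k in range(1, n + 1):
        add_sample(f"seq_ctrl_{k}", medium_exp, role="medium_control_early",
                   replicate=k, group="seq")
        add_sample(f"seq_blank_{k}", floor, role="extraction_control", replicate=k)

    influencers = sorted({i for _, i in pairs})
    for i in influencers:
        exp = spent_expectation(i)
        for k in range(1, n + 1):
            add_sample(f"{i}_spent_{k}", exp, isolate=i, role="spent",
                       replicate=k, group="seq")
            add_sample(f"{i}_abiotic_{k}", exp, role="uninoculated_spent_control",
                       influencer=i, replicate=k, group="seq")

    for r, i in pairs:
        exp = spent_expectation(i).copy()
        c_r = truth.consumption.loc[r].to_numpy()
        exp[: len(metabolites)] *= 1.0 - c_r
        for j, f in enumerate(truth.secreted_features):
            jj = len(metabolites) + j
            amount_i = truth.secretion.loc[i, f]
            if amount_i > 0 and truth.consumability.loc[r, f]:
                exp[jj] = noise.noise_floor + amount_i * (
                    1.0 - truth.secretion_consumed_fraction
                )
            exp[jj] += truth.secretion.loc[r, f]  # recipient's own secretions
        for k in range(1, n + 1):
            add_sample(f"{i}__{r}_double_{k}", exp, role="double_spent",
                       influencer=i, recipient=r, replicate=k, group="seq")

    peaks = PeakHeightTable(
        pd.DataFrame(columns, index=analytes), table_kind="untargeted"
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    # growth of each recipient in each spent medium and in fresh SDM
    t = np.arange(0.0, 48.0 + 1e-9, time_step_h)
    od_rows, resp_rows = [], []
    fresh = truth.consumed_in_fresh()
    recipients = sorted({r for r, _ in pairs})
    true_mis = truth.expected_mis(noise.baseline_median)

    def add_series(iso: str, medium: str, consumed: float) -> None:
        K = truth.n0 + truth.yield_coef.get(iso, 0.0) * consumed if iso else BLANK_OD
        r_rate = truth.growth_rate.get(iso, 1.0) if iso else 1.0
        base = (
            _logistic_series(t, max(K, truth.n0 + 1e-9), truth.n0, r_rate)
            if iso
            else np.full(len(t), BLANK_OD)
        )
        bio_drop = (
            truth.respiration_frac.get(iso, 0.0) * consumed * RESPIRATION_SCALE
            if iso
            else 0.0
        )
        for k in range(1, n + 1):
            od = base * noise.factors(rng, len(t))
            od_rows.append(
                pd.DataFrame(
                    {"isolate": iso, "medium": medium, "replicate": k,
                     "time_h": t, "od600": od}
                )
            )
            drop = CONTROL_A570_DRIFT + bio_drop * float(noise.factors(rng, 1)[0])
            resp_rows.append(
                {"isolate": iso, "medium": medium, "replicate": k,
                 "a570_initial": 1.0, "a570_final": max(1.0 - drop, 0.0)}
            )

    for r in recipients:
        add_series(r, "SDM", float(fresh[r]))
        for i in influencers:
            if r == i:
                continue
            add_series(r, i, truth.consumed_in_spent(r, i, noise.baseline_median))
    add_series("", "SDM", 0.0)
    for i in influencers:
        add_series("", i, 0.0)

    growth = GrowthTable(
        pd.concat(od_rows, ignore_index=True), pd.DataFrame(resp_rows)
    )
    mis = true_mis.loc[recipients, influencers]
    return SequentialExperiment(peaks, meta, growth, mis)


def write_fixture_bundle(
    outdir: str | Path,
    n_isolates: int = 8,
    n_metabolites: int = 60,
    seed: int = 42,
    cv: float = 0.1,
    n_secreted_per_isolate: int = 6,
) -> dict[str, Path]:
    """Emit the CSV bundle consumed by the io layer (and the test suite)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(
        n_isolates=n_isolates,
        n_metabolites=n_metabolites,
        seed=seed,
        n_secreted_per_isolate=n_secreted_per_isolate,
    )
    noise = NoiseModel(cv=cv, seed=seed)
    mono = simulate_monocultures(truth, noise)
    seq = simulate_sequential(mono, noise)

    paths = {
        "mono_peaks": outdir / "mono_peaks.csv",
        "mono_metadata": outdir / "mono_metadata.csv",
        "mono_growth": outdir / "mono_growth.csv",
        "seq_peaks": outdir / "seq_peaks.csv",
        "seq_metadata": outdir / "seq_metadata.csv",
        "seq_growth": outdir / "seq_growth.csv",
        "seq_respiration": outdir / "seq_respiration.csv",
        "true_consumption": outdir / "true_consumption.csv",
        "true_mis": outdir / "true_mis.csv",
    }
    write_matrix(mono.peaks.heights, paths["mono_peaks"])
    mono.metadata.frame.to_csv(paths["mono_metadata"], index=False, lineterminator="\n")
    write_growth_table(mono.growth, paths["mono_growth"])
    write_matrix(seq.peaks.heights, paths["seq_peaks"])
    seq.metadata.frame.to_csv(paths["seq_metadata"], index=False, lineterminator="\n")
    write_growth_table(seq.growth, paths["seq_growth"], paths["seq_respiration"])
    write_matrix(truth.consumption, paths["true_consumption"])
    write_matrix(seq.true_mis, paths["true_mis"])
    return paths
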