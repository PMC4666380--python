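"""End-to-end orchestration: simulate -> (preprocess) -> analyze -> report.

A single :class:`RunConfig` drives one reproducible run.  The simulation
stage generates a fully annotated synthetic experiment (stochastic
amplification + polymerase errors + template switches on a pool of
BC1/BC2 barcode pairs); the analysis stage applies every estimator to the
resulting read-rank profile exactly as it would be applied to real data,
and the report aggregates the fitted distortion parameters.

Every stochastic step derives its Generator from the master seed and a
stage label, so the same seed yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import derive_rng, sample_observed_reads, zero_truncated_poisson
from .bootstrap import PositionSample, bootstrap_uniformity
from .copynum import extended_pdf, fit_pamp, sample_final_copies
from .errors import (
    ErrorRateEstimate,
    _error_sequences,
    attribute_errors,
    estimate_error_rate,
    molecule_error_rate,
)
from .gcbias import estimate_efficiencies, gc_regression
from .preprocess import CountTable
from .profiles import RankProfile, build_profile, poisson_resample
from .switching import (
    assign_classes,
    chimera_read_ratio,
    detect_chimeras,
    estimate_s0,
)
from .templates import BARCODE_LEN, build_input_pool, default_templates


@dataclass
class RunConfig:
    """Parameters of one pipeline run (flat; serialisable to YAML)."""

    seed: int = 0
    n_input: int = 5000
    cycles: int = 25
    p_amp: float = 0.9
    p_nt: float = 2.7e-5
    s0: float = 2.6e-15
    depth_per_input: float = 5000.0  # target mean plateau reads per input
    c_analysis: float = 1.9  # PCR efficiency assumed by the estimators
    pamp_candidates: tuple = (0.8, 0.85, 0.9, 0.95, 0.99)
    fit_n: int = 2900
    resample_lam: float = 0.1
    min_reads: int = 3
    bootstrap_reps: int = 10_000
    class_mix: tuple = (0.5, 0.5)  # BC1-BC1, BC2-BC2
    deterministic_events: bool = False
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pamp_candidates", "class_mix"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("pamp_candidates", "class_mix"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def windows(self) -> dict:
        """Rank windows scaled to the input pool size (reference: 2900)."""
        s = self.n_input / 2900.0
        return {
            "plateau": (0.0, 2900.0 * s),
            "shoulder_tail": (2900.0 * s, 10000.0 * s),
        }


@dataclass
class DistortionEstimates:
    """Aggregated fitted distortion parameters of one run."""

    p_amp_fit: float
    p_amp_r2: dict
    gc_slope: float
    gc_slope_ci95: tuple
    s0_hat: float
    j_k: float
    e_hat: float
    p_nt_hat: float
    f_resampled: float
    f_raw: float
    frac_hamming1: float
    bootstrap_p_switches: float | None
    bootstrap_p_errors: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("p_amp_fit", self.p_amp_fit),
            ("gc_slope", self.gc_slope),
            ("gc_slope_ci_low", self.gc_slope_ci95[0]),
            ("gc_slope_ci_high", self.gc_slope_ci95[1]),
            ("J_k", self.j_k),
            ("s0", self.s0_hat),
            ("F_raw", self.f_raw),
            ("F_resampled", self.f_resampled),
            ("e", self.e_hat),
            ("p_nt", self.p_nt_hat),
            ("frac_hamming1", self.frac_hamming1),
            ("bootstrap_p_switches", self.bootstrap_p_switches),
            ("bootstrap_p_errors", self.bootstrap_p_errors),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value"])


def simulate_experiment(cfg: RunConfig) -> RankProfile:
    """Synthetic barcode-pair experiment with all three distortions.

    Inputs are single molecules whose final copy numbers come from the
    Galton-Watson copy-number PDF.  Error and chimera cohorts are born per
    cycle at their expected rates (``e N_{j-1}`` and ``s0 N_j^2`` with
    ``N_j = N0 (1+P_amp)^j``), receive PDF-distributed final counts for
    the remaining cycles, and are materialised only when sequenced.
    Sequences are real 40-nt barcode pairs so every detector runs as on
    real data; ground truth (origin, birth cycle) travels with each row.
    """
    cfg_rng = derive_rng(cfg.seed, "simulate")
    templates = default_templates()
    mix = {"BC1-BC1": cfg.class_mix[0], "BC2-BC2": cfg.class_mix[1]}
    pool = build_input_pool(cfg.n_input, mix, cfg_rng, templates)
    seqs = [m.barcode_pair for m in pool]
    classes = [m.class_pair for m in pool]
    tags = [m.tag for m in pool]

    p, k = cfg.p_amp, cfg.cycles
    c = 1.0 + p
    e = molecule_error_rate(cfg.p_nt)
    lam = cfg.depth_per_input * cfg.n_input / (cfg.n_input * c**k)

    rows = []
    copies_in = sample_final_copies(cfg.n_input, k, p, cfg_rng)
    reads_in = cfg_rng.poisson(lam * copies_in.astype(float))
    for i in range(cfg.n_input):
        if reads_in[i] > 0:
            rows.append((seqs[i], int(reads_in[i]), "input", 0, classes[i], tags[i]))

    def cohort(j, expected_born):
        """Observed rows (copies drawn read-weighted from the remaining-
        cycles PDF, then zero-truncated Poisson reads)."""
        n_born = (
            int(round(expected_born))
            if cfg.deterministic_events
            else int(cfg_rng.poisson(expected_born))
        )
        if n_born == 0:
            return np.zeros(0, dtype=np.int64)
        rem = k - j
        if rem == 0:
            support, probs = np.array([1.0]), np.array([1.0])
        else:
            pdf = extended_pdf(rem, p)
            support, probs = pdf.copies.astype(float), pdf.probs
        w = -np.expm1(-np.clip(lam * support, 0, 700))
        p_obs = float(np.dot(probs, w))
        if p_obs <= 0:
            return np.zeros(0, dtype=np.int64)
        n_obs = int(cfg_rng.binomial(n_born, p_obs))
        if n_obs == 0:
            return np.zeros(0, dtype=np.int64)
        cond = probs * w / p_obs
        obs_copies = cfg_rng.choice(support, size=n_obs, p=cond / cond.sum())
        return zero_truncated_poisson(lam * obs_copies, cfg_rng)

    for j in range(1, k + 1):
        n_j_prev = cfg.n_input * c ** (j - 1)
        err_reads = cohort(j, e * n_j_prev)
        if err_reads.size:
            parent_idx = cfg_rng.integers(cfg.n_input, size=err_reads.size)
            err_seqs = _error_sequences(seqs, parent_idx, cfg_rng)
            rows.extend(
                (s, int(r), "error", j, classes[pi], tags[pi])
                for s, r, pi in zip(err_seqs, err_reads, parent_idx)
            )
        sw_reads = cohort(j, cfg.s0 * (n_j_prev * c) ** 2)
        if sw_reads.size:
            a_idx = cfg_rng.integers(cfg.n_input, size=sw_reads.size)
            b_idx = cfg_rng.integers(cfg.n_input, size=sw_reads.size)
            rows.extend(
                (
                    seqs[a][:BARCODE_LEN] + seqs[b][BARCODE_LEN:],
                    int(r),
                    "switch",
                    j,
                    (classes[a][0], classes[b][1]),
                    tags[b],
                )
                for a, b, r in zip(a_idx, b_idx, sw_reads)
            )

    df = pd.DataFrame(
        rows, columns=["sequence", "reads", "origin", "birth_cycle", "class_pair", "tag"]
    )
    df = (
        df.groupby("sequence", as_index=False, sort=False)
        .agg(
            reads=("reads", "sum"),
            origin=("origin", "first"),
            birth_cycle=("birth_cycle", "min"),
            class_pair=("class_pair", "first"),
            tag=("tag", "first"),
        )
    )
    profile = build_profile(df, windows=cfg.windows)
    profile.df.attrs.update({"lam": lam, "e_molecule": e})
    return profile


def analyze_profile(profile: RankProfile, cfg: RunConfig) -> DistortionEstimates:
    """Apply every estimator to a (synthetic or real) annotated profile."""
    templates = default_templates()
    k, c = cfg.cycles, cfg.c_analysis

    # --- stochastic amplification: fit P_amp on the plateau -------------
    fit_rng = derive_rng(cfg.seed, "fit_pamp")
    n_fit = min(cfg.fit_n if cfg.n_input >= 2900 else cfg.n_input, cfg.n_input)
    best_p, r2 = fit_pamp(
        profile, cfg.pamp_candidates, n_input=cfg.n_input,
        rng=fit_rng, total_cycles=k,
    )

    # --- GC bias over the plateau ---------------------------------------
    plateau = profile.window_rows("plateau")
    gc_table = estimate_efficiencies(plateau, cycles=k, ref_eff=c)
    reg = gc_regression(gc_table)

    # --- template switching ---------------------------------------------
    table = CountTable(
        profile.df.rename(columns={"reads": "read_count"})[
            ["sequence", "read_count"]
        ].assign(distinct_tag_count=1)
    )
    assign_classes(table, templates)
    class_df = profile.df.assign(class_pair=table.df["class_pair"].to_numpy())
    chim = detect_chimeras(CountTable(class_df.rename(columns={"reads": "read_count"})), profile)
    j_k = chimera_read_ratio(class_df)
    n0_plateau = int(profile.window_mask("plateau").sum())
    s0_hat = estimate_s0(j_k, N0=n0_plateau, c=c, k=k)

    # positions are bootstrapped over the full observed rank range
    boot_rng = derive_rng(cfg.seed, "bootstrap")
    full_window = (0.0, float(profile.scaled_rank.max()))
    sw_pos = chim["scaled_rank"].to_numpy()
    p_sw = None
    if sw_pos.size >= 2:
        p_sw = bootstrap_uniformity(
            PositionSample(sw_pos, full_window, reps=cfg.bootstrap_reps), boot_rng
        ).p_value

    # --- polymerase errors ----------------------------------------------
    attrib = attribute_errors(profile, min_reads=cfg.min_reads)
    thin_rng = derive_rng(cfg.seed, "resample")
    thinned = poisson_resample(profile, cfg.resample_lam, thin_rng)
    attrib_thin = attribute_errors(thinned, min_reads=1)
    est: ErrorRateEstimate = estimate_error_rate(attrib_thin.f_reads, k=k, c=c)

    from .errors import detect_anchor_errors

    anchor_rows = detect_anchor_errors(profile, templates)
    err_pos = anchor_rows["scaled_rank"].to_numpy()
    p_err = None
    if err_pos.size >= 2:
        p_err = bootstrap_uniformity(
            PositionSample(err_pos, full_window, reps=cfg.bootstrap_reps), boot_rng
        ).p_value

    return DistortionEstimates(
        p_amp_fit=best_p,
        p_amp_r2=r2,
        gc_slope=reg.slope,
        gc_slope_ci95=reg.ci95,
        s0_hat=s0_hat,
        j_k=j_k,
        e_hat=est.e,
        p_nt_hat=est.p_nt_linear,
        f_resampled=attrib_thin.f_reads,
        f_raw=attrib.f_reads,
        frac_hamming1=attrib.frac_distance1,
        bootstrap_p_switches=p_sw,
        bootstrap_p_errors=p_err,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Full reproducible run; returns the report bundle and optionally
    writes all tables under ``cfg.outdir``."""
    t0 = time.time()
    profile = simulate_experiment(cfg)
    t1 = time.time()
    estimates = analyze_profile(profile, cfg)
    t2 = time.time()
    report = {
        "estimates": estimates,
        "profile": profile,
        "timings": {"simulate_s": t1 - t0, "analyze_s": t2 - t1},
        "provenance": {
            "package_version": __version__,
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
        },
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        profile.to_tsv(out / "rank_profile.tsv")
        estimates.to_frame().to_csv(out / "estimates.tsv", sep="\t", index=False)
        cfg.to_yaml(out / "config.yaml")
        prov = dict(report["provenance"])
        prov["timings"] = report["timings"]
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, default=str)
    return report
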