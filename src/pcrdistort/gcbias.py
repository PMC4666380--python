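"""GC-dependent PCR efficiency: estimation, regression and simulation.

Per-sequence PCR efficiencies are inferred from plateau read counts: with
every input present as a single molecule before PCR, the relative
abundance after 25 cycles reflects the per-cycle efficiency.  Abundances
``m_x`` are normalised to the mean of the 0.50-0.55 GC bin, which is
assigned the reference efficiency 1.9, giving
``c_x = (m_x * 1.9^25)^(1/25)``.  Efficiencies are averaged in GC bins of
width 0.05 and regressed on GC content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import as_rng
from .profiles import RankProfile, build_profile
from .simulate import SequencingModel, poisson_sequencing_sample

REF_BIN = (0.50, 0.55)
BIN_WIDTH = 0.05


def gc_content(seq: str) -> float:
    """Fraction of G+C in an ACGT sequence."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class EfficiencyTable:
    """Per-sequence and per-GC-bin PCR efficiencies.

    ``per_sequence`` columns: sequence, gc, reads, m_x, c_x.
    ``per_bin`` columns: bin_low, bin_high, c, n_sequences.
    The reference bin carries efficiency ``ref_eff`` by construction.
    """

    per_sequence: pd.DataFrame
    per_bin: pd.DataFrame
    cycles: int = 25
    ref_eff: float = 1.9
    ref_bin: tuple[float, float] = REF_BIN

    def bin_efficiency(self, gc: np.ndarray) -> np.ndarray:
        """Efficiency of the bin containing each GC value; missing bins
        inherit the nearest populated bin."""
        lows = self.per_bin["bin_low"].to_numpy()
        cs = self.per_bin["c"].to_numpy()
        own_low = _gc_bin_low(np.asarray(gc, dtype=float))
        idx = np.abs(own_low[:, None] - lows[None, :]).argmin(axis=1)
        return cs[idx]

    def to_tsv(self, path) -> None:
        self.per_bin.to_csv(path, sep="\t", index=False)


def _gc_bin_low(gc: np.ndarray) -> np.ndarray:
    """Left edge of the width-0.05 bin: [x, x+0.05); gc == 1.0 joins the last bin."""
    low = np.floor(np.asarray(gc, dtype=float) / BIN_WIDTH) * BIN_WIDTH
    return np.where(np.isclose(gc, 1.0), 1.0 - BIN_WIDTH, low).round(10)


def estimate_efficiencies(
    plateau_rows: pd.DataFrame | RankProfile,
    cycles: int = 25,
    ref_eff: float = 1.9,
) -> EfficiencyTable:
    """Efficiency table from plateau rows (needs ``sequence`` and ``reads``).

    ``m_x`` = reads / mean reads of the reference-bin sequences;
    ``c_x = (m_x * ref_eff^cycles)^(1/cycles)``.
    """
    if isinstance(plateau_rows, RankProfile):
        plateau_rows = plateau_rows.window_rows("plateau")
    df = plateau_rows.copy()
    if "reads" not in df.columns:
        df = df.rename(columns={"read_count": "reads"})
    if "gc" not in df.columns:
        df["gc"] = [gc_content(s) for s in df["sequence"]]
    in_ref = (df["gc"] >= REF_BIN[0]) & (df["gc"] < REF_BIN[1])
    if not in_ref.any():
        raise ValueError(
            f"no plateau sequence in the reference GC bin [{REF_BIN[0]}, {REF_BIN[1]})"
        )
    ref_mean = df.loc[in_ref, "reads"].mean()
    df["m_x"] = df["reads"] / ref_mean
    df["c_x"] = ref_eff * df["m_x"] ** (1.0 / cycles)
    df["bin_low"] = _gc_bin_low(df["gc"].to_numpy())
    per_bin = (
        df.groupby("bin_low")
        .agg(c=("c_x", "mean"), n_sequences=("c_x", "size"))
        .reset_index()
    )
    per_bin["bin_high"] = (per_bin["bin_low"] + BIN_WIDTH).round(10)
    per_bin = per_bin[["bin_low", "bin_high", "c", "n_sequences"]]
    out_of_range = df[(df["c_x"] < 1.0) | (df["c_x"] > 2.0)]
    table = EfficiencyTable(
        per_sequence=df[["sequence", "gc", "reads", "m_x", "c_x"]],
        per_bin=per_bin,
        cycles=cycles,
        ref_eff=ref_eff,
    )
    table.per_sequence.attrs["n_outside_1_2"] = len(out_of_range)
    return table


@dataclass
class GcRegression:
    slope: float
    intercept: float
    ci95: tuple[float, float]
    r_value: float
    n: int


def gc_regression(table: EfficiencyTable, per_sequence: bool = True) -> GcRegression:
    """OLS of efficiency on GC content with a t-based 95% CI on the slope.

    Per-sequence efficiencies by default (more data); per-bin by flag.
    """
    if per_sequence:
        x = table.per_sequence["gc"].to_numpy()
        y = table.per_sequence["c_x"].to_numpy()
    else:
        x = (table.per_bin["bin_low"] + BIN_WIDTH / 2).to_numpy()
        y = table.per_bin["c"].to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 points for the GC regression")
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    half = tcrit * fit.stderr
    return GcRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        ci95=(float(fit.slope - half), float(fit.slope + half)),
        r_value=float(fit.rvalue),
        n=len(x),
    )


def simulate_gc_biased_pcr(
    table: EfficiencyTable,
    sequencing_model: SequencingModel,
    rng,
    n_input: int = 2900,
    cycles: int = 25,
    barcode_len: int = 40,
) -> RankProfile:
    """Deterministic GC-biased PCR of ``n_input`` single-copy inputs.

    GC content per sequence ~ Binomial(40, 0.5)/40; each sequence grows as
    ``c_bin^cycles`` with the efficiency of its GC bin; Poisson sequencing.
    """
    rng = as_rng(rng)
    gc = rng.binomial(barcode_len, 0.5, size=n_input) / barcode_len
    eff = table.bin_efficiency(gc)
    copies = eff.astype(float) ** cycles
    reads = poisson_sequencing_sample(copies, sequencing_model, rng)
    df = pd.DataFrame(
        {
            "sequence": [f"gcsim_{i:06d}" for i in range(n_input)],
            "reads": reads,
            "gc": gc,
            "origin": "input",
        }
    )
    df = df[df["reads"] > 0]
    if df.empty:
        raise ValueError("no reads sampled; increase sequencing depth")
    return build_profile(df)
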