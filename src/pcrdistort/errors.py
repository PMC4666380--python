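"""Polymerase errors: detection, rate estimation and simulation.

An erroneous copy lags its parent by at least one cycle, so error-derived
sequences populate the shoulder and tail of the read-rank profile.  Two
detectors are used: minimum Hamming distance of non-plateau sequences to
the plateau (parent) sequences, and purine/pyrimidine anchor violations
(an RY or YR dinucleotide anchor cannot occur in the input pool).

With faithful molecules growing as ``R_j = N0 c^j`` and a per-molecule
per-cycle error probability ``e``, new errors on cycle j number
``E_j = e R_{j-1}``; accumulated over k cycles the erroneous molecules are
``Z_k = N0 e k c^(k-1)`` and the erroneous read fraction is
``F_k = Z_k / R_k = k e / c``, which inverts to ``e = F_k c / k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_rng, sample_observed_reads, zero_truncated_poisson
from .copynum import extended_pdf, sample_final_copies
from .profiles import RankProfile, build_profile, poisson_resample
from .templates import BARCODE_LEN, AmpliconTemplate, default_templates

PAIR_LEN = 2 * BARCODE_LEN


def analytic_error_prob(p_nt: float, length: int = PAIR_LEN) -> tuple[float, float]:
    """Per-molecule error probability over ``length`` nucleotides and the
    expected number of molecules per error (its reciprocal; inf at 0)."""
    if not 0.0 <= p_nt <= 1.0:
        raise ValueError("p_nt must be in [0, 1]")
    p = 1.0 - (1.0 - p_nt) ** length
    return p, (1.0 / p if p > 0 else np.inf)


def repeated_sequencing_error_prob(
    phred: int = 30, n_repeats: int = 3, length: int = PAIR_LEN
) -> float:
    """Probability that the same base-calling error recurs ``n_repeats``
    times somewhere in a ``length``-nt sequence at the given quality."""
    per_base = 10.0 ** (-phred / 10.0)
    return length * per_base**n_repeats


def molecule_error_rate(p_nt: float, length: int = PAIR_LEN) -> float:
    return 1.0 - (1.0 - p_nt) ** length


def _as_matrix(seqs) -> np.ndarray:
    seqs = list(seqs)
    if not seqs:
        return np.zeros((0, PAIR_LEN), dtype=np.uint8)
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def min_hamming_to_set(seq: str, parents) -> int:
    """Minimum substitution distance from ``seq`` to a set of equal-length
    parent sequences (exact brute force)."""
    parents = list(parents)
    if not parents:
        raise ValueError("parent set must not be empty")
    if any(len(p) != len(seq) for p in parents):
        raise ValueError("sequences must all have equal length")
    mat = _as_matrix(parents)
    q = np.frombuffer(seq.encode(), dtype=np.uint8)
    return int((mat != q[None, :]).sum(axis=1).min())


def _pack_onehot(mat: np.ndarray) -> np.ndarray:
    """Pack base rows (uint8 ACGT) into 4-bit one-hot uint64 words.

    XOR of two packed rows then sets exactly two bits per mismatching
    base, so Hamming distance = popcount(xor) / 2.
    """
    n, length = mat.shape
    codes = np.zeros_like(mat, dtype=np.uint64)
    for i, b in enumerate(b"ACGT"):
        codes[mat == b] = i
    n_words = (4 * length + 63) // 64
    out = np.zeros((n, n_words), dtype=np.uint64)
    for i in range(length):
        w, base_off = divmod(4 * i, 64)
        out[:, w] |= np.uint64(1) << (np.uint64(base_off) + codes[:, i])
    return out


def _min_hamming_batch(queries: np.ndarray, parents: np.ndarray) -> np.ndarray:
    """Chunked minimum Hamming distances of query rows to parent rows."""
    qp = _pack_onehot(queries)
    pp = _pack_onehot(parents)
    out = np.empty(queries.shape[0], dtype=np.int64)
    chunk = max(1, int(2**24 // max(parents.shape[0], 1)))
    for a in range(0, qp.shape[0], chunk):
        x = np.bitwise_count(qp[a : a + chunk, None, :] ^ pp[None, :, :]).sum(
            axis=2, dtype=np.int64
        )
        out[a : a + chunk] = x.min(axis=1) // 2
    return out


@dataclass
class ErrorAttribution:
    """Hamming-distance attribution of non-plateau sequences to the plateau."""

    distance_hist: dict[int, int]  # over rows with reads >= min_reads
    frac_distance1: float  # fraction of those rows at distance 1
    n_attributed: int
    n_ambiguous: int  # rows below min_reads (sequencing/PCR origin unclear)
    frac_distance1_all: float  # over all non-plateau rows regardless of reads
    positions: np.ndarray  # scaled ranks of distance-1 rows
    f_reads: float  # distance-1 read sum over plateau read sum


def attribute_errors(
    profile: RankProfile,
    plateau_window: str = "plateau",
    min_reads: int = 3,
) -> ErrorAttribution:
    """Attribute non-plateau rows to single-substitution errors.

    Parents are the plateau sequences.  Rows with ``reads >= min_reads``
    (below that an Illumina sequencing error cannot be excluded) enter the
    distance histogram; the distance-1 fraction is reported both for those
    rows and for all non-plateau rows.
    """
    mask = profile.window_mask(plateau_window)
    plateau = profile.df.loc[mask]
    others = profile.df.loc[~mask]
    if plateau.empty:
        raise ValueError("plateau window is empty")
    if others.empty:
        return ErrorAttribution({}, 0.0, 0, 0, 0.0, np.zeros(0), 0.0)
    parents = _as_matrix(plateau["sequence"])
    queries = _as_matrix(others["sequence"])
    dists = _min_hamming_batch(queries, parents)
    reads = others["reads"].to_numpy()
    confident = reads >= min_reads
    hist_vals, hist_counts = np.unique(dists[confident], return_counts=True)
    d1 = dists == 1
    frac_conf = (
        float((d1 & confident).sum() / confident.sum()) if confident.any() else 0.0
    )
    positions = profile.scaled_rank[~mask][d1]
    f_reads = float(reads[d1].sum() / plateau["reads"].sum())
    return ErrorAttribution(
        distance_hist=dict(zip(hist_vals.tolist(), hist_counts.tolist())),
        frac_distance1=frac_conf,
        n_attributed=int(confident.sum()),
        n_ambiguous=int((~confident).sum()),
        frac_distance1_all=float(d1.mean()),
        positions=positions,
        f_reads=f_reads,
    )


def detect_anchor_errors(
    profile_or_df,
    templates: dict[str, AmpliconTemplate] | None = None,
) -> pd.DataFrame:
    """Rows containing any mixed (RY/YR) dinucleotide anchor.

    Such anchors cannot occur in the input pool, so each flagged row
    carries at least one substitution.  Returns the flagged rows with
    their scaled ranks when a profile is given.
    """
    templates = templates or default_templates()
    if isinstance(profile_or_df, RankProfile):
        df = profile_or_df.df
        ranks = profile_or_df.scaled_rank
    else:
        df = profile_or_df
        ranks = None
    arr = _as_matrix(df["sequence"])
    is_purine = (arr == ord("A")) | (arr == ord("G"))
    t1 = templates["BC1-BC1"]
    mixed = np.zeros(arr.shape[0], dtype=bool)
    for slot in range(2):
        for a, b in t1.dinucleotide_anchors(slot):
            col_a = is_purine[:, a + slot * BARCODE_LEN]
            col_b = is_purine[:, b + slot * BARCODE_LEN]
            mixed |= col_a != col_b
    out = df.loc[mixed].copy()
    if ranks is not None:
        out["scaled_rank"] = ranks[mixed]
    return out


@dataclass
class ErrorRateEstimate:
    e: float  # per molecule per cycle
    p_nt_exact: float  # exact inversion over 40 nt
    p_nt_linear: float  # e / 40 linearisation


def estimate_error_rate(F_k: float, k: int = 25, c: float = 1.9) -> ErrorRateEstimate:
    """Invert ``F_k = k e / c`` for the per-molecule error rate."""
    if not 0.0 <= F_k < 1.0:
        raise ValueError("F_k must be in [0, 1)")
    e = F_k * c / k
    return ErrorRateEstimate(
        e=e,
        p_nt_exact=1.0 - (1.0 - e) ** (1.0 / PAIR_LEN),
        p_nt_linear=e / PAIR_LEN,
    )


@dataclass
class ErrorLoad:
    r_j: np.ndarray  # faithful molecules, j = 0..k
    e_j: np.ndarray  # new errors per cycle, j = 1..k
    z_k: float  # cumulative erroneous molecules
    f_k: float  # erroneous read fraction k e / c


def error_load(N0: int, e: float, c: float, k: int) -> ErrorLoad:
    """Closed-form error load of the deterministic model."""
    if not 1.0 < c <= 2.0:
        raise ValueError("PCR efficiency c must be in (1, 2]")
    j = np.arange(0, k + 1)
    r_j = N0 * c ** j.astype(float)
    e_j = e * r_j[:-1]
    z_k = N0 * e * k * c ** (k - 1.0)
    return ErrorLoad(r_j=r_j, e_j=e_j, z_k=float(z_k), f_k=float(k * e / c))


def _error_sequences(parent_seqs: list[str], parent_idx: np.ndarray, rng) -> list[str]:
    """One uniform single substitution of a parent per requested row."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = []
    pos = rng.integers(PAIR_LEN, size=parent_idx.size)
    pick = rng.integers(3, size=parent_idx.size)
    for i, (pi, po, pk) in enumerate(zip(parent_idx, pos, pick)):
        arr = np.frombuffer(parent_seqs[pi].encode(), dtype=np.uint8).copy()
        arr[po] = bases[bases != arr[po]][pk]
        out.append(arr.tobytes().decode())
    return out


def simulate_erroneous_pcr(
    p_nt: float,
    sequencing_model,
    rng,
    N0: int = 2900,
    c: float = 1.9,
    cycles: int = 25,
    deterministic_events: bool = True,
    input_sequences: list[str] | None = None,
) -> RankProfile:
    """Erroneous PCR on a background of deterministic efficiency-``c`` PCR.

    Inputs grow as ``c^j``.  New unique error sequences appear on cycle j
    at the expected rate ``e R_{j-1}`` (a Poisson draw unless
    ``deterministic_events``) and grow as ``c^(k-j)``.  Only rows reaching
    at least one sequencing read are materialised.  If ``input_sequences``
    is given (one 40-nt barcode pair per input), error rows carry actual
    single-substitution sequences; otherwise synthetic row ids are used.
    """
    rng = as_rng(rng)
    e = molecule_error_rate(p_nt)
    input_copies = float(c) ** cycles
    lam = sequencing_model.solve_lam(np.full(N0, input_copies))
    with_seqs = input_sequences is not None
    if with_seqs and len(input_sequences) != N0:
        raise ValueError("need one input sequence per input molecule")
    rows = []
    input_reads = rng.poisson(lam * input_copies, size=N0)
    for i, r in enumerate(input_reads):
        if r > 0:
            name = input_sequences[i] if with_seqs else f"in_{i:06d}"
            rows.append((name, int(r), "input", 0))
    true_error_molecules = 0.0
    for j in range(1, cycles + 1):
        expected = e * N0 * float(c) ** (j - 1)
        n_born = (
            int(round(expected)) if deterministic_events else int(rng.poisson(expected))
        )
        copies = float(c) ** (cycles - j)
        true_error_molecules += n_born * copies
        reads = sample_observed_reads(n_born, lam * copies, rng)
        if reads.size == 0:
            continue
        if with_seqs:
            parent_idx = rng.integers(N0, size=reads.size)
            seqs = _error_sequences(input_sequences, parent_idx, rng)
        else:
            seqs = [f"err_{j:02d}_{m:06d}" for m in range(reads.size)]
        rows.extend(
            (s, int(r), "error", j) for s, r in zip(seqs, reads)
        )
    df = pd.DataFrame(rows, columns=["sequence", "reads", "origin", "birth_cycle"])
    df = df.groupby(["sequence", "origin", "birth_cycle"], as_index=False, sort=False)[
        "reads"
    ].sum()
    profile = build_profile(df)
    profile.df.attrs.update(
        {
            "lam": lam,
            "e_molecule": e,
            "true_error_molecules": true_error_molecules,
            "input_molecules": N0 * input_copies,
        }
    )
    return profile


def simulate_stochastic_with_errors(
    p_nt: float,
    sequencing_model,
    rng,
    N0: int = 2900,
    p_amp: float = 0.9,
    cycles: int = 25,
    deterministic_events: bool = False,
    input_sequences: list[str] | None = None,
) -> RankProfile:
    """Galton-Watson PCR with polymerase errors.

    Every input and every new error sequence receives a final molecule
    count sampled from the copy-number PDF after ``cycles - x`` cycles,
    where x is the cycle at which it first arose (exact PDF up to 15
    cycles, Gaussian-extended beyond).  Error birth counts per cycle
    follow the expected molecule numbers ``e N0 (1 + P_amp)^(j-1)``.
    Rows are materialised only if sequenced (>= 1 read): per cohort the
    observation probability ``E[1 - exp(-lam n)]`` is computed from the
    copy-number PDF and copies for observed rows are drawn from the
    read-weighted PDF.
    """
    rng = as_rng(rng)
    e = molecule_error_rate(p_nt)
    c = 1.0 + p_amp
    lam = sequencing_model.solve_lam(np.full(N0, float(c) ** cycles))
    with_seqs = input_sequences is not None
    if with_seqs and len(input_sequences) != N0:
        raise ValueError("need one input sequence per input molecule")

    rows = []
    copies_in = sample_final_copies(N0, cycles, p_amp, rng)
    input_reads = rng.poisson(lam * copies_in.astype(float))
    for i in range(N0):
        if input_reads[i] > 0:
            name = input_sequences[i] if with_seqs else f"in_{i:06d}"
            rows.append((name, int(input_reads[i]), "input", 0))

    true_error_molecules = 0.0
    for j in range(1, cycles + 1):
        expected_born = e * N0 * c ** (j - 1)
        n_born = (
            int(round(expected_born))
            if deterministic_events
            else int(rng.poisson(expected_born))
        )
        if n_born == 0:
            continue
        rem = cycles - j
        if rem == 0:
            support = np.array([1.0])
            probs = np.array([1.0])
        else:
            pdf = extended_pdf(rem, p_amp)
            support, probs = pdf.copies.astype(float), pdf.probs
        true_error_molecules += n_born * float(np.dot(support, probs))
        w = -np.expm1(-np.clip(lam * support, 0, 700))
        p_obs = float(np.dot(probs, w))
        if p_obs <= 0:
            continue
        n_obs = int(rng.binomial(n_born, p_obs))
        if n_obs == 0:
            continue
        cond = probs * w / p_obs
        cond = cond / cond.sum()
        obs_copies = rng.choice(support, size=n_obs, p=cond)
        reads = zero_truncated_poisson(lam * obs_copies, rng)
        if with_seqs:
            parent_idx = rng.integers(N0, size=n_obs)
            seqs = _error_sequences(input_sequences, parent_idx, rng)
        else:
            seqs = [f"err_{j:02d}_{m:06d}" for m in range(n_obs)]
        rows.extend((s, int(r), "error", j) for s, r in zip(seqs, reads))

    df = pd.DataFrame(rows, columns=["sequence", "reads", "origin", "birth_cycle"])
    df = df.groupby(["sequence", "origin", "birth_cycle"], as_index=False, sort=False)[
        "reads"
    ].sum()
    profile = build_profile(df)
    profile.df.attrs.update(
        {
            "lam": lam,
            "e_molecule": e,
            "true_error_molecules": true_error_molecules,
            "input_molecules": float(copies_in.sum()),
        }
    )
    return profile


def error_read_fraction(
    profile: RankProfile,
    rng,
    resample_lam: float = 0.1,
    min_reads: int = 3,
) -> dict[str, float]:
    """F_k before and after Poisson(lam=0.1) resampling of the read counts.

    The resampling removes low-read rows whose mismatches could be
    sequencing errors; the ratio of Hamming-1 tail reads to plateau reads
    is invariant under the thinning in expectation.
    """
    raw = attribute_errors(profile, min_reads=min_reads)
    thinned = poisson_resample(profile, resample_lam, rng)
    res = attribute_errors(thinned, min_reads=1)
    return {"f_raw": raw.f_reads, "f_resampled": res.f_reads}
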