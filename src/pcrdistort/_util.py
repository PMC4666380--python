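"""Shared numerical helpers: seeding, truncated-Poisson sampling."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, ``None`` or a Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """Deterministically derive a stage-specific Generator from a master seed.

    Mixing the CRC32 of the stage label keeps the streams of different
    pipeline stages independent while remaining reproducible from one
    integer seed.
    """
    mixed = (int(master_seed) ^ zlib.crc32(label.encode())) & MAX_SEED
    return np.random.default_rng(mixed)


def zero_truncated_poisson(mu, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Sample from Poisson(mu) conditioned on being >= 1.

    ``mu`` may be a scalar (with ``size`` draws) or an array of per-draw
    rates.  Inverse-transform over the truncated pmf; exact for any mu > 0
    and fast when mu is small (the common case: rows that barely reach one
    read).
    """
    mu = np.asarray(mu, dtype=float)
    if mu.ndim == 0:
        if size is None:
            raise ValueError("size is required for scalar mu")
        mu = np.full(size, float(mu))
    n = mu.size
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if (mu <= 0).any():
        raise ValueError("zero-truncated Poisson requires mu > 0")
    out = np.ones(n, dtype=np.int64)
    big = mu > 30  # P(0) < 1e-13: plain Poisson is indistinguishable
    if big.any():
        out[big] = np.maximum(rng.poisson(mu[big]), 1)
    small = ~big
    if small.any():
        m = mu[small]
        u = rng.random(small.sum()) * -np.expm1(-m)  # uniform over (0, 1 - e^-mu)
        term = np.exp(-m) * m  # pmf at k = 1
        cdf = term.copy()  # truncated running sum P(1..k)
        res = np.ones(small.sum(), dtype=np.int64)
        pending = u > cdf
        k = 1
        while pending.any():
            k += 1
            term = term * m / k
            cdf = cdf + term
            res[pending] = k
            pending = u > cdf
            if k > 10_000:  # pragma: no cover - unreachable safety stop
                break
        out[small] = res
    return out


def sample_observed_reads(
    n_rows: int | float,
    mu: float,
    rng: np.random.Generator,
    deterministic_rows: bool = False,
) -> np.ndarray:
    """Read counts (>= 1) for the subset of a cohort of rows that is sequenced.

    A cohort of ``n_rows`` molecules-turned-rows each receives
    Poisson(``mu``) reads.  Only rows with at least one read are ever
    observable, so we draw how many are observed and then their
    zero-truncated read counts, instead of materialising the (possibly
    enormous) unobserved majority.
    """
    if mu <= 0 or n_rows <= 0:
        return np.zeros(0, dtype=np.int64)
    p_seen = -np.expm1(-mu)
    if deterministic_rows:
        n_seen = int(round(n_rows * p_seen))
    else:
        n_seen = int(rng.binomial(int(round(n_rows)), p_seen))
    if n_seen == 0:
        return np.zeros(0, dtype=np.int64)
    return zero_truncated_poisson(mu, rng, size=n_seen)
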