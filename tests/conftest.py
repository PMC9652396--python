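"""Shared fixtures: one default synthetic study, reused across test modules."""

import numpy as np
import pytest

from chromage.simulate import (SimConfig, generate_annotation,
                               generate_counts, generate_fragments)

SEED = 1  # the generator's default study seed


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=SEED)


@pytest.fixture(scope="session")
def annotation(default_config):
    return generate_annotation(default_config)


@pytest.fixture(scope="session")
def sim_counts(default_config, annotation):
    return generate_counts(annotation, default_config)


@pytest.fixture(scope="session")
def fragments_and_map(default_config, annotation):
    return generate_fragments(annotation, default_config)


@pytest.fixture(scope="session")
def atac_records_by_ct(sim_counts):
    from chromage.pipeline import differential_by_cell_type
    return differential_by_cell_type(sim_counts.atac)


# ---------------------------------------------------------------- oracles

def mask_union(intervals, genome_lengths):
    """Per-bp boolean-mask union of intervals, as disjoint spans."""
    out = []
    for chrom, length in genome_lengths:
        mask = np.zeros(length, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                mask[iv.start:iv.end] = True
        edges = np.flatnonzero(np.diff(np.concatenate(
            [[0], mask.view(np.int8), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            out.append((chrom, int(lo), int(hi)))
    return out


def bh_stepup_bruteforce(p):
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    from scipy.stats import hypergeom
    n = a + b + c + d
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())


def nb_grid_loglik_max(y, lib, phi, lo=-45.0, hi=15.0):
    """Grid maximisation of the NB log-likelihood over the shared log rate."""
    from scipy.special import gammaln

    def ll(t):
        mu = np.exp(t)[:, None] * lib[None, :]
        r = 1.0 / phi
        return (gammaln(y[None, :] + r) - gammaln(r) - gammaln(y[None, :] + 1)
                + r * np.log(r / (r + mu))
                + y[None, :] * np.log(mu / (r + mu))).sum(axis=1)

    grid = np.linspace(lo, hi, 2001)
    for _ in range(4):
        vals = ll(grid)
        k = int(np.argmax(vals))
        lo_, hi_ = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        grid = np.linspace(lo_, hi_, 401)
    return float(ll(grid).max())
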