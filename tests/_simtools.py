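"""Shared simulation helpers for the test suite.

These build hybrid-level trait vectors directly (polygenic + residual, with
optional planted marker effects) so calibration and recovery tests can work
on the adjusted-mean scale without re-running the field-trial stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from testcross_gwas.gwas import vanraden_grm
from testcross_gwas.simulate import SimConfig, hybrid_id, simulate_founders, tester_labels


def founder_panel(n_fathers, n_markers, seed, within_block_corr=0.0,
                  ld_block_length=10, n_chromosomes=5):
    """Founder dosages with the requested marker count; corr=0 gives
    independent null markers."""
    mpc = n_markers // n_chromosomes
    cfg = SimConfig(n_fathers=n_fathers, n_chromosomes=n_chromosomes,
                    markers_per_chromosome=mpc, ld_block_length=ld_block_length,
                    within_block_corr=within_block_corr, noise_marker_fraction=0.0,
                    seed=seed)
    geno, bounds, _ = simulate_founders(cfg)
    return geno, bounds


def hybrid_frame(fathers, n_testers=2):
    testers = tester_labels(n_testers)
    rows = {hybrid_id(f, t): {"father": f, "mother": t} for f in fathers for t in testers}
    return pd.DataFrame.from_dict(rows, orient="index")


def polygenic_values(geno_dosages, sigma2, rng):
    """Father effects ~ N(0, sigma2 * GRM / mean diag)."""
    G = vanraden_grm(geno_dosages).matrix.to_numpy()
    G = G / np.mean(np.diag(G))
    L = np.linalg.cholesky(sigma2 * G + 1e-8 * np.eye(G.shape[0]))
    return pd.Series(L @ rng.standard_normal(G.shape[0]), index=geno_dosages.index)


def hybrid_means(geno, hybrids, rng, s2_poly=1.0, s2_resid=1.0, mother_effect=0.0,
                 qtl=None, trait="trait"):
    """One trait of hybrid-level means: mother + QTL + polygenic + residual.

    ``qtl``: list of (marker id, effect per dosage unit), dosages centered.
    """
    fathers = hybrids["father"]
    y = np.zeros(len(hybrids))
    if mother_effect:
        ref = sorted(hybrids["mother"].unique())[0]
        y = y + mother_effect * (hybrids["mother"] != ref).to_numpy(float)
    for marker, eff in qtl or []:
        d = geno.dosages[marker]
        y = y + eff * fathers.map(d - d.mean()).to_numpy()
    if s2_poly > 0:
        poly = polygenic_values(geno.dosages, s2_poly, rng)
        y = y + fathers.map(poly).to_numpy()
    y = y + rng.normal(0.0, np.sqrt(s2_resid), size=len(hybrids))
    return pd.DataFrame({trait: y}, index=hybrids.index)


def brute_force_blocks(ld, r2_min, tolerance):
    """Literal replay of the seeding/extension/tolerance rules.

    Kept deliberately naive (sets, rescans, explicit pending buffers) as an
    independent oracle for the production block builder.  ``ld`` is a plain
    2-D array; returns a list of sorted member-index lists.
    """
    M = len(ld)
    unassigned = set(range(M))
    found = []
    while True:
        # seed: unassigned adjacent pair of maximal r^2, leftmost on ties
        candidates = [i for i in range(M - 1) if i in unassigned and i + 1 in unassigned]
        if not candidates:
            break
        best = max(ld[i][i + 1] for i in candidates)
        if best < r2_min:
            break
        seed = min(i for i in candidates if ld[i][i + 1] == best)
        members = {seed, seed + 1}

        # rightward walk from the right conforming edge
        edge = seed + 1
        pending = []
        j = edge + 1
        while j < M and j in unassigned:
            if ld[j][edge] >= r2_min:
                members.update(pending)
                members.add(j)
                pending = []
                edge = j
            else:
                pending.append(j)
                if len(pending) > tolerance:
                    break
            j += 1

        # leftward walk from the left conforming edge
        edge = seed
        pending = []
        j = edge - 1
        while j >= 0 and j in unassigned:
            if ld[j][edge] >= r2_min:
                members.update(pending)
                members.add(j)
                pending = []
                edge = j
            else:
                pending.append(j)
                if len(pending) > tolerance:
                    break
            j -= 1

        found.append(sorted(members))
        unassigned -= members
    return sorted(found)
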