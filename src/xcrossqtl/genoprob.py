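"""Map-function utilities and conditional QTL-genotype probabilities.

A backcross individual carries one recombinant F1 gamete on a background of
recurrent-parent chromosomes, so each locus has two genotype classes:
``A`` (homozygous recurrent parent) and ``H`` (heterozygous).  Along a
chromosome the true genotype sequence is a two-state Markov chain whose
transition probabilities are recombination fractions from the Haldane map
function (no crossover interference).  Observed marker genotypes are noisy
emissions with a symmetric genotyping-error rate ``error_prob``; missing
genotypes are uninformative.  Conditional genotype probabilities at markers
and at pseudomarkers inserted every ``step_cm`` are computed exactly by the
forward-backward algorithm, chromosome by chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GENOTYPE_A, GENOTYPE_H, CrossPopulation

logger = logging.getLogger(__name__)

DEFAULT_STEP_CM = 1.0
DEFAULT_ERROR_PROB = 1e-4


def haldane(cm):
    """Map distance (cM) -> recombination fraction, r = (1 - exp(-2d/100))/2."""
    d = np.asarray(cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0 cM")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def haldane_inverse(r):
    """Recombination fraction -> map distance (cM); requires r in [0, 0.5)."""
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * rr)
    return d if d.ndim else float(d)


@dataclass
class GenotypeProbabilities:
    """P(A), P(H) for every individual at every evaluation position.

    ``positions`` columns: chrom, cm, is_marker, name, nearest_marker.
    ``probs`` has shape (n_individuals, n_positions, 2) with class order
    (A, H); rows sum to one at every cell.
    """

    positions: pd.DataFrame
    probs: np.ndarray
    individuals: pd.Index
    step_cm: float
    error_prob: float

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.positions["chrom"].to_numpy() == str(chrom))

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def to_tsv(self, path) -> None:
        pos = self.positions
        records = []
        for i, ind in enumerate(self.individuals):
            df = pos[["chrom", "cm", "name"]].copy()
            df.insert(0, "individual", ind)
            df["p_a"] = self.probs[i, :, 0]
            df["p_h"] = self.probs[i, :, 1]
            records.append(df)
        pd.concat(records).to_csv(path, sep="\t", index=False, float_format="%.8g")


def _evaluation_grid(marker_cm: np.ndarray, step_cm: float) -> np.ndarray:
    """Marker positions plus pseudomarkers every ``step_cm`` (0 = markers only)."""
    if step_cm < 0:
        raise ValueError("step_cm must be >= 0")
    if step_cm == 0 or len(marker_cm) == 1:
        grid = np.unique(np.round(marker_cm, 9))
    else:
        pseudo = np.arange(marker_cm[0], marker_cm[-1] + 1e-9, step_cm)
        grid = np.unique(np.round(np.concatenate([marker_cm, pseudo]), 9))
    return grid


def conditional_genotype_probs(
    cross: CrossPopulation,
    step_cm: float = DEFAULT_STEP_CM,
    error_prob: float = DEFAULT_ERROR_PROB,
) -> GenotypeProbabilities:
    """Exact forward-backward genotype probabilities on a pseudomarker grid."""
    if not 0 <= error_prob < 0.5:
        raise ValueError("error_prob must be in [0, 0.5)")
    gmap = cross.gmap
    n = cross.n_individuals
    pos_frames: list[pd.DataFrame] = []
    prob_blocks: list[np.ndarray] = []
    if "X" in gmap.chromosomes or "x" in gmap.chromosomes:
        logger.info("X chromosome present; treated as autosomal")
    for chrom in gmap.chromosomes:
        sub = gmap.markers_on(chrom)
        mcm = sub["cm"].to_numpy(dtype=float)
        names = sub["marker"].tolist()
        grid = _evaluation_grid(mcm, step_cm)
        g_of_marker = np.searchsorted(grid, np.round(mcm, 9))

        # emissions, product over markers that share a grid position
        emis = np.ones((n, len(grid), 2))
        for name, g in zip(names, g_of_marker):
            obs = cross.genotypes[name].to_numpy(dtype=object)
            e_a = np.where(obs == GENOTYPE_A, 1.0 - error_prob,
                           np.where(obs == GENOTYPE_H, error_prob, 1.0))
            e_h = np.where(obs == GENOTYPE_H, 1.0 - error_prob,
                           np.where(obs == GENOTYPE_A, error_prob, 1.0))
            emis[:, g, 0] *= e_a
            emis[:, g, 1] *= e_h

        prob_blocks.append(_forward_backward(emis, haldane(np.diff(grid))))

        is_marker = np.zeros(len(grid), dtype=bool)
        is_marker[g_of_marker] = True
        pos_names = np.array(
            [f"c{chrom}.loc{g:g}" for g in grid], dtype=object
        )
        pos_names[g_of_marker] = names
        nearest = np.searchsorted(mcm, grid)
        nearest = np.clip(nearest, 0, len(mcm) - 1)
        left = np.clip(nearest - 1, 0, len(mcm) - 1)
        use_left = np.abs(grid - mcm[left]) <= np.abs(mcm[nearest] - grid)
        nearest_idx = np.where(use_left, left, nearest)
        pos_frames.append(
            pd.DataFrame(
                {
                    "chrom": str(chrom),
                    "cm": grid,
                    "is_marker": is_marker,
                    "name": pos_names,
                    "nearest_marker": [names[i] for i in nearest_idx],
                }
            )
        )

    positions = pd.concat(pos_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1) if prob_blocks else np.zeros((n, 0, 2))
    return GenotypeProbabilities(
        positions, probs, cross.individual_ids, step_cm, error_prob
    )


def _forward_backward(emis: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Posterior state probabilities of the two-state chain.

    emis: (n, G, 2) emission likelihoods; r: (G-1,) recombination fractions
    between adjacent grid positions.  Prior at any position is (1/2, 1/2).
    """
    n, G, _ = emis.shape
    tiny = 1e-300
    alphas = np.empty((G, n, 2))
    a = 0.5 * emis[:, 0, :]
    a /= np.maximum(a.sum(1, keepdims=True), tiny)
    alphas[0] = a
    for j in range(1, G):
        rj = r[j - 1]
        t = np.array([[1.0 - rj, rj], [rj, 1.0 - rj]])
        a = (a @ t) * emis[:, j, :]
        a /= np.maximum(a.sum(1, keepdims=True), tiny)
        alphas[j] = a

    post = np.empty((n, G, 2))
    b = np.ones((n, 2))
    post[:, G - 1, :] = alphas[G - 1]
    for j in range(G - 2, -1, -1):
        rj = r[j]
        t = np.array([[1.0 - rj, rj], [rj, 1.0 - rj]])
        b = (emis[:, j + 1, :] * b) @ t
        b /= np.maximum(b.sum(1, keepdims=True), tiny)
        p = alphas[j] * b
        post[:, j, :] = p / np.maximum(p.sum(1, keepdims=True), tiny)
    return post
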