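"""EM estimation of two-locus gamete (haplotype) frequencies.

Within one stratum of unphased genotype counts at two diallelic loci, every
genotype class determines its pair of gametes uniquely except the double
heterozygote, which is a mixture of the coupling (AB/ab) and repulsion
(Ab/aB) phase configurations.  The EM algorithm therefore reduces to
splitting the double-heterozygote count each iteration in proportion
h00*h11 : h01*h10 and re-normalising gamete counts.

Gametes are indexed (k, l) by risk-allele carrier state at loci G and H:
h00 = ab, h01 = aB, h10 = Ab, h11 = AB.  The EM update conserves the allele
margins, so the fitted allele frequencies always equal the direct
genotype-count allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GameteFrequencies", "em_gamete_frequencies", "observed_loglik"]


@dataclass(frozen=True)
class GameteFrequencies:
    """EM-fitted four-gamete distribution for one stratum."""

    h: np.ndarray  # shape (2, 2): h[k, l]
    allele_freq_g: float
    allele_freq_h: float
    loglik: float
    n_iter: int
    converged: bool
    notes: str = ""

    @property
    def as_matrix(self) -> np.ndarray:
        return self.h

    @property
    def d_linkage(self) -> float:
        """Gametic disequilibrium D = h11 - p_G * p_H."""
        return float(self.h[1, 1] - self.allele_freq_g * self.allele_freq_h)


def _decompose(counts, levels_g, levels_h):
    """Split genotype counts into phase-determined gamete counts and the
    double-heterozygote count.

    Returns (fixed, n_dh, n) where ``fixed`` is a 2x2 array of gamete counts
    contributed by phase-unambiguous cells (two gametes per individual).
    """
    counts = np.asarray(counts, dtype=float)
    fixed = np.zeros((2, 2))
    n_dh = 0.0
    for a, g in enumerate(levels_g):
        for b, h in enumerate(levels_h):
            ncell = counts[a, b]
            if ncell == 0:
                continue
            if g == 1 and h == 1:
                n_dh += ncell
                continue
            if g == 1:  # het at G only: gametes (1, h/2) and (0, h/2)
                l = h // 2
                fixed[1, l] += ncell
                fixed[0, l] += ncell
            elif h == 1:  # het at H only
                k = g // 2
                fixed[k, 1] += ncell
                fixed[k, 0] += ncell
            else:  # both homozygous: two identical gametes
                fixed[g // 2, h // 2] += 2 * ncell
    return fixed, n_dh, counts.sum()


def observed_loglik(counts, h, levels_g=None, levels_h=None) -> float:
    """Observed-data multinomial log-likelihood of genotype counts under
    random union of gametes with frequencies ``h``.

    ``P(double het) = 2(h00*h11 + h01*h10)``; all other cells are the usual
    products of their (unique) gamete pair, with a factor 2 when the pair is
    heterozygous at exactly one locus.  Returns ``-inf`` when a cell with
    positive count has probability zero.
    """
    counts = np.asarray(counts, dtype=float)
    h = np.asarray(h, dtype=float).reshape(2, 2)
    if abs(h.sum() - 1.0) > 1e-8 or (h < -1e-12).any():
        raise ValueError("h must be a probability vector over the four gametes")
    if levels_g is None:
        levels_g = tuple(range(counts.shape[0]))
    if levels_h is None:
        levels_h = tuple(range(counts.shape[1]))
    ll = 0.0
    for a, g in enumerate(levels_g):
        for b, hh in enumerate(levels_h):
            ncell = counts[a, b]
            if ncell == 0:
                continue
            if g == 1 and hh == 1:
                p = 2.0 * (h[0, 0] * h[1, 1] + h[0, 1] * h[1, 0])
            elif g == 1:
                l = hh // 2
                p = 2.0 * h[1, l] * h[0, l]
            elif hh == 1:
                k = g // 2
                p = 2.0 * h[k, 1] * h[k, 0]
            else:
                p = h[g // 2, hh // 2] ** 2
            if p <= 0.0:
                return float("-inf")
            ll += ncell * np.log(p)
    return float(ll)


def em_gamete_frequencies(
    counts,
    levels_g=None,
    levels_h=None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> GameteFrequencies:
    """Fit the four gamete frequencies of one stratum by EM.

    Initialisation is the linkage-equilibrium product of the observed allele
    frequencies (deterministic).  Iteration stops when the largest absolute
    frequency change or the log-likelihood change drops below ``tol``.
    When the data carry no phase information at all (every individual a
    double heterozygote) the linkage-equilibrium point is a stationary point
    of the likelihood; it is returned flagged ``degenerate``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D genotype count matrix")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if levels_g is None:
        levels_g = tuple(range(counts.shape[0]))
    if levels_h is None:
        levels_h = tuple(range(counts.shape[1]))
    fixed, n_dh, n = _decompose(counts, levels_g, levels_h)
    if n == 0:
        raise ValueError("total count is zero")

    # allele frequencies from genotype counts (conserved by every EM step)
    p_g = float(sum(counts[a, :].sum() * g for a, g in enumerate(levels_g)) / (2 * n))
    p_h = float(sum(counts[:, b].sum() * h for b, h in enumerate(levels_h)) / (2 * n))
    h = np.array([[(1 - p_g) * (1 - p_h), (1 - p_g) * p_h],
                  [p_g * (1 - p_h), p_g * p_h]])

    notes = ""
    if n_dh == n and n_dh > 0:
        notes = "degenerate: all individuals doubly heterozygous; phase non-identifiable"
        ll = observed_loglik(counts, h, levels_g, levels_h)
        return GameteFrequencies(h, p_g, p_h, ll, 0, True, notes)

    ll = observed_loglik(counts, h, levels_g, levels_h)
    converged = n_dh == 0 or max_iter == 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        coup = h[0, 0] * h[1, 1]
        rep = h[0, 1] * h[1, 0]
        w = 0.5 if coup + rep == 0 else coup / (coup + rep)
        gam = fixed.copy()
        gam[0, 0] += n_dh * w
        gam[1, 1] += n_dh * w
        gam[0, 1] += n_dh * (1 - w)
        gam[1, 0] += n_dh * (1 - w)
        h_new = gam / (2 * n)
        ll_new = observed_loglik(counts, h_new, levels_g, levels_h)
        delta = np.abs(h_new - h).max()
        h = h_new
        dll = ll_new - ll
        ll = ll_new
        if delta < tol or abs(dll) < tol:
            converged = True
            break
        if n_dh == 0:
            converged = True
            break
    if not converged:
        notes = f"EM did not converge within {max_iter} iterations"
    h = np.clip(h, 0.0, 1.0)
    return GameteFrequencies(h, p_g, p_h, float(ll), n_iter, converged, notes)
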