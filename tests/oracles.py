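"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: direct
histogram WHAM instead of the binless estimator, all-pairs enumeration
instead of vectorized MSD/contact code, and hit-or-miss integration for
union volumes.
"""

from __future__ import annotations

import numpy as np


def binned_wham(windows, bin_width: float = 1.0):
    """Classic binned WHAM on a fixed histogram grid.

    Solves the binned WHAM maximum-likelihood problem directly: the profile
    is parameterized by per-bin log-probabilities g(N) (occupied bins only)
    and the standard likelihood

        L(g) = sum_k sum_N h_k(N) [g(N) - ln sum_M exp(g(M) - u_k(M))]

    is maximized with scipy (plain WHAM iteration stalls when windows share
    few bins). Returns (bin_centers, beta_f) with beta_f min-shifted to
    zero, restricted to occupied bins.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    all_samples = np.concatenate([w.samples for w in windows])
    lo = np.floor(all_samples.min() - 0.5 * bin_width)
    hi = np.ceil(all_samples.max() + 0.5 * bin_width)
    edges = np.arange(lo - bin_width / 2, hi + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2

    hist = np.zeros((len(windows), len(centers)))
    for k, w in enumerate(windows):
        hist[k], _ = np.histogram(w.samples, bins=edges)
    occupied = hist.sum(axis=0) > 0
    centers = centers[occupied]
    hist = hist[:, occupied]
    n_k = hist.sum(axis=1)
    total = hist.sum(axis=0)
    u = np.stack(
        [0.5 * w.kappa_kt * (centers - w.nstar) ** 2 for w in windows]
    )

    def neg_log_lik(g):
        # per-window log partition functions ln Z_k = ln sum_N e^{g - u_k}
        log_z = logsumexp(g[None, :] - u, axis=1)
        val = -(np.sum(total * g) - np.sum(n_k * log_z))
        w_kn = np.exp(g[None, :] - u - log_z[:, None])
        grad = -(total - n_k @ w_kn)
        return val, grad

    g0 = np.log(np.maximum(total, 0.5) / total.sum())
    res = minimize(neg_log_lik, g0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-10})
    g = res.x - logsumexp(res.x)
    beta_f = -g
    return centers, beta_f - beta_f.min()


def brute_force_msd(frames, xy, max_lag):
    """All-pairs time-averaged MSD of one track (frame indices may gap)."""
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    n = len(frames)
    for i in range(n):
        for j in range(i + 1, n):
            lag = frames[j] - frames[i]
            if lag <= max_lag:
                sums[lag - 1] += np.sum((xy[j] - xy[i]) ** 2)
                counts[lag - 1] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


def brute_force_contact_map(frames, cutoff, min_sep):
    """Per-frame pairwise loop version of the contact-frequency matrix."""
    n_frames, n_sites, _ = frames.shape
    freq = np.zeros((n_sites, n_sites))
    for f in range(n_frames):
        for i in range(n_sites):
            for j in range(n_sites):
                if abs(i - j) < min_sep:
                    continue
                d = np.linalg.norm(frames[f, i] - frames[f, j])
                if d <= cutoff:
                    freq[i, j] += 1
    return freq / n_frames


def brute_force_hbonds(donors, hydrogens, acceptors, d_cut, angle_cut_deg):
    """Scalar-loop geometric hydrogen-bond counter."""
    count = 0
    for d_pos, h_pos in zip(donors, hydrogens):
        for a_pos in acceptors:
            if np.linalg.norm(a_pos - d_pos) > d_cut:
                continue
            v1 = d_pos - h_pos
            v2 = a_pos - h_pos
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle >= 180.0 - angle_cut_deg:
                count += 1
    return count


def double_well_beta_f(n_min=0, n_max=70, well_a=10, well_b=35, barrier=4.0):
    """Tabulated quartic double-well with equal wells and a known barrier."""
    n = np.arange(n_min, n_max + 1)
    mid = (well_b - well_a) / 2.0
    f = barrier * ((n - well_a) * (n - well_b) / mid**2) ** 2
    return n, f
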