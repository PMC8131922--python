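"""MaxLFQ protein intensity: pairwise median log-ratios reconciled by least squares.

For a protein with M quantified peptide ions over N experiments, every
experiment pair (i, j) sharing at least one ion contributes the median of
the per-ion log-ratios m_ij = median_p[log I_i(p) - log I_j(p)].  The
log protein intensities x solve the normal system A x = b where

    A_ii = number of experiments sharing >= 1 ion with i,   A_ij = -1(i, j)
    b_i  = sum_j m_ij over defined pairs

The system is singular up to an additive constant per connected component of
the shared-ion graph; each component is solved by Cholesky on a minimally
regularized A and re-anchored so that the component's mean log intensity
equals the mean of the summed-ion log intensities (MaxLFQ convention).
Protein intensity in experiment i is exp(x_i).
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve


@dataclasses.dataclass
class RatioSummary:
    """N x N median log-ratio matrix with a defined-pair mask."""

    m: np.ndarray
    defined: np.ndarray  # boolean, True where >= 1 shared ion

    @property
    def n(self) -> int:
        return self.m.shape[0]


@dataclasses.dataclass
class LfqSystem:
    A: np.ndarray
    b: np.ndarray
    defined: np.ndarray


def median_log_ratios(I: np.ndarray) -> RatioSummary:
    """Median log-ratios between experiment rows of an N x M intensity matrix.

    Missing intensities are NaN (or <= 0, treated as missing).  Entries of
    ``m`` are NaN where no shared ion exists; defined entries satisfy
    m_ij = -m_ji and the diagonal is undefined.
    """
    I = np.asarray(I, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(I > 0, np.log(I), np.nan)
    n = I.shape[0]
    m = np.full((n, n), np.nan)
    defined = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            diff = L[i] - L[j]
            diff = diff[~np.isnan(diff)]
            if diff.size:
                med = float(np.median(diff))
                m[i, j] = med
                m[j, i] = -med
                defined[i, j] = defined[j, i] = True
    return RatioSummary(m=m, defined=defined)


def assemble_system(R: RatioSummary) -> LfqSystem:
    """Build the least-squares normal system A x = b from median ratios."""
    n = R.n
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and R.defined[i, j]:
                A[i, j] = -1.0
                A[i, i] += 1.0
                b[i] += R.m[i, j]
    return LfqSystem(A=A, b=b, defined=R.defined)


def _components(defined: np.ndarray, active: np.ndarray) -> list[list[int]]:
    """Connected components of the shared-ion graph over active experiments."""
    n = defined.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s] or not active[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if not seen[v] and active[v] and defined[u, v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def solve_lfq(system: LfqSystem, anchors: np.ndarray) -> np.ndarray:
    """Solve for log protein intensities x (NaN for experiments without ions).

    ``anchors`` holds per-experiment log summed-ion intensities (NaN where
    the experiment has no ion of this protein); each connected component's
    solution is shifted so mean(x) = mean(anchors) over the component.
    """
    anchors = np.asarray(anchors, dtype=float)
    n = system.A.shape[0]
    x = np.full(n, np.nan)
    active = ~np.isnan(anchors)
    for comp in _components(system.defined, active):
        idx = np.asarray(comp)
        if idx.size == 1:
            x[idx[0]] = anchors[idx[0]]
            continue
        A = system.A[np.ix_(idx, idx)].copy()
        b = system.b[idx]
        eps = 1e-10 * np.trace(A) / idx.size
        A[np.diag_indices_from(A)] += eps
        sol = cho_solve(cho_factor(A), b)
        sol += np.mean(anchors[idx]) - np.mean(sol)
        x[idx] = sol
    return x


def maxlfq_intensities(I: np.ndarray) -> tuple[np.ndarray, int]:
    """Protein intensities exp(x_i) for an N x M ion intensity matrix.

    Returns (intensities, number of connected components among quantified
    experiments).  Experiments with no quantified ion get NaN.
    """
    I = np.asarray(I, dtype=float)
    I = np.where(I > 0, I, np.nan)
    R = median_log_ratios(I)
    system = assemble_system(R)
    sums = np.nansum(np.where(np.isnan(I), 0.0, I), axis=1)
    has_ion = (~np.isnan(I)).any(axis=1)
    anchors = np.where(has_ion, np.log(np.where(sums > 0, sums, 1.0)), np.nan)
    x = solve_lfq(system, anchors)
    ncomp = len(_components(system.defined, has_ion))
    return np.exp(x), ncomp


def protein_table(
    ion_rows: pd.DataFrame,
    run_ids: list[str],
    min_ions: int = 2,
) -> pd.DataFrame:
    """Per-protein MaxLFQ intensities from a long ion table.

    ``ion_rows`` columns: ``protein``, ``run_id``, ``ion``, ``intensity``.
    Proteins with fewer than ``min_ions`` distinct ions over the whole study
    are dropped.  Output: one row per protein with one intensity column per
    run, the study-wide ion count and the connected-component count.
    """
    records = []
    run_index = {r: k for k, r in enumerate(run_ids)}
    for protein, grp in ion_rows.groupby("protein", sort=True):
        ions = sorted(grp["ion"].unique())
        if len(ions) < min_ions:
            continue
        ion_index = {io: k for k, io in enumerate(ions)}
        I = np.full((len(run_ids), len(ions)), np.nan)
        for row in grp.itertuples(index=False):
            I[run_index[row.run_id], ion_index[row.ion]] = row.intensity
        intensities, ncomp = maxlfq_intensities(I)
        rec = {"protein": protein, "n_ions": len(ions), "n_components": ncomp}
        for r in run_ids:
            v = intensities[run_index[r]]
            rec[f"intensity_{r}"] = float(v) if np.isfinite(v) else np.nan
        records.append(rec)
    cols = ["protein", "n_ions", "n_components"] + [f"intensity_{r}" for r in run_ids]
    return pd.DataFrame(records, columns=cols)
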