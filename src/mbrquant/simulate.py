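"""Synthetic multi-run DDA experiments with complete ground truth.

The generator emulates the benchmark designs used to validate transfer FDR
and quantification accuracy:

* a **two-organism** design - a set of runs containing only "human"
  proteins plus a set containing a human/yeast mixture, so that any yeast
  ion transferred into a human-only run is a ground-truth false transfer;
* a **three-species** design - two conditions (A, B) in which human, yeast
  and E. coli proteins are mixed at known ratios (1:1, 2:1, 1:4), giving
  ground-truth protein fold changes.

Each run's peak map contains planted 0/+1/+2 isotope envelopes at
monotonically warped retention times with jitter, log-normal ion
intensities with optional per-run scale factors, intensity-biased MS/MS
sampling that drives missingness, and chemical-noise features drawn from a
peptide-like m/z pool (real peptide signals crowd discrete ~1.0005
Th-spaced mass clusters, which is what makes shifted-m/z decoy transfers
traceable).  A fixed seed reproduces the experiment bit for bit.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .model import IonKey, PROTON_MASS, PsmRecord, QuantRow, RunPeakMap

#: true C13-C12 spacing used when planting isotopes (the tracer's averaged
#: constant differs slightly; the ppm tolerance absorbs the gap).
C13_SPACING = 1.0033548378

_AA = "ACDEFGHIKLMNPQRSTVWY"
# average monoisotopic residue mass used to size random sequences
_MEAN_RESIDUE = 111.1


@dataclasses.dataclass
class SimConfig:
    """Study conditions of a simulated experiment.

    Defaults describe the two-organism benchmark: 8 human-only + 8
    human/yeast runs over a 20-min gradient, 125 proteins x 16 ions
    (~2000 ions), 12.5% yeast proteins, dense chemical noise.
    """

    design: str = "two_organism"  # "two_organism" | "three_species" | "uniform"
    n_runs_h: int = 8
    n_runs_hy: int = 8
    n_replicates: int = 3  # per condition, three_species design
    n_proteins: int = 125
    ions_per_protein: int = 16
    yeast_fraction: float = 0.125
    species_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    # condition multipliers A/B per species (three_species design)
    ratios: tuple[tuple[float, float], ...] = ((1.0, 1.0), (2.0, 1.0), (1.0, 4.0))
    # chromatography
    rt_range: tuple[float, float] = (5.0, 25.0)
    scan_interval: float = 0.02
    chrom_sigma_range: tuple[float, float] = (0.04, 0.08)
    rt_warp_knots: int = 3
    rt_warp_sd: float = 0.3
    rt_jitter_sd: float = 0.05
    # intensities
    log_intensity_mean: float = math.log(1e6)
    log_intensity_sd: float = 1.2
    run_intensity_noise_sd: float = 0.15
    scan_noise_sd: float = 0.05
    run_scale_factors: tuple[float, ...] | None = None
    # MS/MS sampling (logistic in log intensity)
    msms_detect_max: float = 0.97
    msms_detect_mid: float = math.log(5e4)
    msms_detect_scale: float = 0.8
    msms_rt_error_sd: float = 0.03
    # mass dimension
    mass_range: tuple[float, float] = (800.0, 1500.0)
    charges: tuple[int, ...] = (2, 3)
    mz_ppm_sd: float = 1.5
    # chemical noise
    noise_features: int = 20000
    noise_pool: int = 6000
    noise_log_intensity_mean: float = math.log(5e4)
    noise_log_intensity_sd: float = 1.0
    noise_sigma_range: tuple[float, float] = (0.03, 0.06)
    # optional dimensions
    with_im: bool = False
    im_range: tuple[float, float] = (0.7, 1.4)
    faims_cvs: tuple[float, ...] | None = None
    seed: int = 0


@dataclasses.dataclass
class SimulatedExperiment:
    """Peak maps, PSM table and ground truth of one simulated study."""

    config: SimConfig
    peak_maps: dict[str, RunPeakMap]
    psms: list[PsmRecord]
    ions: pd.DataFrame       # ion_id, sequence, charge, mz, mass, protein, species, ...
    planted: pd.DataFrame    # run_id, ion_id, apex_rt, intensity, detected
    run_conditions: dict[str, str]  # run_id -> sample label (H / HY / A / B)

    @property
    def run_ids(self) -> list[str]:
        return sorted(self.peak_maps)

    def ion_key(self, ion_id: int) -> IonKey:
        row = self.ions.loc[ion_id]
        return IonKey(row["sequence"], "", int(row["charge"]))

    @property
    def planted_set(self) -> set[tuple[str, IonKey]]:
        """(run_id, IonKey) pairs whose signal truly exists in the run."""
        keys = {i: self.ion_key(i) for i in self.ions.index}
        return {(r.run_id, keys[r.ion_id]) for r in self.planted.itertuples(index=False)}


def _random_peptide(rng: np.random.Generator, mass_target: float) -> str:
    n = max(6, int(round(mass_target / _MEAN_RESIDUE)))
    return "".join(rng.choice(list(_AA), size=n))


def _sequence_mass(seq: str) -> float:
    from pyteomics import mass as _m

    return _m.fast_mass(seq)


def _make_warp(rng: np.random.Generator, cfg: SimConfig):
    """Monotone piecewise-linear RT warp with <= rt_warp_knots interior knots."""
    lo, hi = cfg.rt_range
    knots = np.concatenate([[lo], np.sort(rng.uniform(lo, hi, cfg.rt_warp_knots)), [hi]])
    offsets = rng.normal(0.0, cfg.rt_warp_sd, knots.size)
    warped = knots + offsets
    warped = np.maximum.accumulate(warped + np.arange(knots.size) * 1e-9)

    def warp(t: np.ndarray) -> np.ndarray:
        return np.interp(t, knots, warped)

    return warp


def _profile_rows(scans, apex, sigma, height, mz, rng, scan_noise_sd, span=3.0):
    """Vectorized Gaussian elution profiles sampled on the scan grid.

    All inputs are per-feature arrays; returns flat (mz, rt, intensity,
    feature_index) row arrays covering scans within ``span`` sigmas of each
    apex.  ``feature_index`` maps every row back to its source feature.
    """
    s0 = np.searchsorted(scans, apex - span * sigma)
    s1 = np.searchsorted(scans, apex + span * sigma)
    counts = s1 - s0
    keep = counts > 0
    orig = np.flatnonzero(keep)
    s0, counts = s0[keep], counts[keep]
    apex, sigma, height, mz = apex[keep], sigma[keep], height[keep], mz[keep]
    total = int(counts.sum())
    if total == 0:
        return (np.empty(0),) * 3 + (np.empty(0, dtype=np.intp),)
    cum = np.cumsum(counts)
    offs = np.arange(total) - np.repeat(cum - counts, counts)
    scan_idx = np.repeat(s0, counts) + offs
    t = scans[scan_idx]
    y = np.repeat(height, counts) * np.exp(
        -0.5 * ((t - np.repeat(apex, counts)) / np.repeat(sigma, counts)) ** 2
    )
    if scan_noise_sd > 0:
        y = y * np.exp(rng.normal(0.0, scan_noise_sd, total))
    return np.repeat(mz, counts), t, y, np.repeat(orig, counts)


def simulate_experiment(cfg: SimConfig) -> SimulatedExperiment:
    """Generate peak maps, PSMs and truth tables for the configured design."""
    rng = np.random.default_rng(cfg.seed)
    lo_rt, hi_rt = cfg.rt_range

    # --- runs and species design --------------------------------------
    if cfg.design == "two_organism":
        runs = [f"H{i+1:02d}" for i in range(cfg.n_runs_h)] + \
               [f"HY{i+1:02d}" for i in range(cfg.n_runs_hy)]
        conditions = {r: ("H" if r.startswith("H") and not r.startswith("HY") else "HY")
                      for r in runs}
        n_yeast = int(round(cfg.n_proteins * cfg.yeast_fraction))
        species_of = ["yeast"] * n_yeast + ["human"] * (cfg.n_proteins - n_yeast)
    elif cfg.design == "three_species":
        runs = [f"A{i+1}" for i in range(cfg.n_replicates)] + \
               [f"B{i+1}" for i in range(cfg.n_replicates)]
        conditions = {r: r[0] for r in runs}
        fr = cfg.species_fractions
        n_h = int(round(cfg.n_proteins * fr[0]))
        n_y = int(round(cfg.n_proteins * fr[1]))
        species_of = ["human"] * n_h + ["yeast"] * n_y + \
                     ["ecoli"] * (cfg.n_proteins - n_h - n_y)
    elif cfg.design == "uniform":
        runs = [f"R{i+1:02d}" for i in range(cfg.n_runs_h)]
        conditions = {r: "R" for r in runs}
        species_of = ["human"] * cfg.n_proteins
    else:
        raise ValueError(f"unknown design {cfg.design!r}")
    ratio_of = dict(zip(("human", "yeast", "ecoli"), cfg.ratios))

    # --- ions ----------------------------------------------------------
    n_ions = cfg.n_proteins * cfg.ions_per_protein
    mass_targets = np.exp(rng.uniform(math.log(cfg.mass_range[0]),
                                      math.log(cfg.mass_range[1]), n_ions))
    ion_records = []
    seqs_seen: set[str] = set()
    for i in range(n_ions):
        seq = _random_peptide(rng, mass_targets[i])
        while seq in seqs_seen:
            seq = _random_peptide(rng, mass_targets[i])
        seqs_seen.add(seq)
        charge = int(rng.choice(cfg.charges))
        mass = _sequence_mass(seq)
        protein_idx = i // cfg.ions_per_protein
        ion_records.append({
            "ion_id": i,
            "sequence": seq,
            "charge": charge,
            "mass": mass,
            "mz": mass / charge + PROTON_MASS,
            "protein": f"P{protein_idx:04d}",
            "species": species_of[protein_idx],
            "base_rt": rng.uniform(lo_rt + 0.5, hi_rt - 0.5),
            "sigma": rng.uniform(*cfg.chrom_sigma_range),
            "im": rng.uniform(*cfg.im_range) if cfg.with_im else np.nan,
            "base_log_intensity": rng.normal(cfg.log_intensity_mean,
                                             cfg.log_intensity_sd),
        })
    ions = pd.DataFrame(ion_records).set_index("ion_id")
    lam = 4.9384e-4 * ions["mass"].to_numpy()
    raw = np.stack([np.ones(n_ions), lam, lam ** 2 / 2.0], axis=1)
    iso_p = raw / raw.sum(axis=1, keepdims=True)

    # --- chemical noise pool (peptide-like m/z values) ------------------
    pool_mass = np.exp(rng.uniform(math.log(cfg.mass_range[0]),
                                   math.log(cfg.mass_range[1]), cfg.noise_pool))
    # snap to the discrete peptide mass-cluster grid with a realistic defect spread
    cluster = np.round(pool_mass)
    pool_mass = cluster * 1.000495 + rng.normal(0.0, 0.01, cfg.noise_pool)
    pool_charge = rng.choice(cfg.charges, cfg.noise_pool)
    pool_mz = pool_mass / pool_charge + PROTON_MASS

    run_scales = cfg.run_scale_factors
    if run_scales is None:
        run_scales = tuple(1.0 for _ in runs)
    if len(run_scales) != len(runs):
        raise ValueError("run_scale_factors length must match run count")

    faims_of_ion = None
    if cfg.faims_cvs:
        faims_of_ion = rng.choice(cfg.faims_cvs, n_ions)
        faims_of_noise = rng.choice(cfg.faims_cvs, cfg.noise_pool)

    peak_maps: dict[str, RunPeakMap] = {}
    psms: list[PsmRecord] = []
    planted_rows = []

    base_rt = ions["base_rt"].to_numpy()
    sigma = ions["sigma"].to_numpy()
    mz0 = ions["mz"].to_numpy()
    charge_arr = ions["charge"].to_numpy()
    base_log_i = ions["base_log_intensity"].to_numpy()
    species_arr = ions["species"].to_numpy()
    im_arr = ions["im"].to_numpy()

    for run_pos, run in enumerate(runs):
        cond = conditions[run]
        warp = _make_warp(rng, cfg)
        phase = rng.uniform(0.0, cfg.scan_interval)
        scans = np.arange(lo_rt - 1.0 + phase, hi_rt + 1.0, cfg.scan_interval)

        # species present in this run, with condition intensity multiplier
        if cfg.design == "two_organism":
            present = np.ones(n_ions, dtype=bool) if cond == "HY" \
                else species_arr == "human"
            mult = np.ones(n_ions)
        elif cfg.design == "three_species":
            present = np.ones(n_ions, dtype=bool)
            col = 0 if cond == "A" else 1
            mult = np.array([ratio_of[s][col] for s in species_arr])
        else:
            present = np.ones(n_ions, dtype=bool)
            mult = np.ones(n_ions)

        idx = np.flatnonzero(present)
        apex = warp(base_rt[idx]) + rng.normal(0.0, cfg.rt_jitter_sd, idx.size)
        inten = np.exp(base_log_i[idx]
                       + rng.normal(0.0, cfg.run_intensity_noise_sd, idx.size)) \
            * mult[idx] * run_scales[run_pos]
        run_mz = mz0[idx] * (1.0 + rng.normal(0.0, cfg.mz_ppm_sd, idx.size) * 1e-6)

        mz_parts, rt_parts, y_parts, im_parts, cv_parts = [], [], [], [], []
        ion_height = inten / (sigma[idx] * math.sqrt(2 * math.pi))
        for k in range(3):
            mz_k = run_mz + k * C13_SPACING / charge_arr[idx]
            h_k = ion_height * iso_p[idx, k]
            m, t, y, feat = _profile_rows(scans, apex, sigma[idx], h_k, mz_k, rng,
                                          cfg.scan_noise_sd)
            mz_parts.append(m)
            rt_parts.append(t)
            y_parts.append(y)
            if cfg.with_im:
                im_parts.append(im_arr[idx][feat])
            if cfg.faims_cvs:
                cv_parts.append(faims_of_ion[idx][feat])

        # chemical noise features
        if cfg.noise_features > 0:
            n_noise = cfg.noise_features
            pick = rng.integers(0, cfg.noise_pool, n_noise)
            n_rt = rng.uniform(lo_rt, hi_rt, n_noise)
            n_sig = rng.uniform(*cfg.noise_sigma_range, n_noise)
            n_int = np.exp(rng.normal(cfg.noise_log_intensity_mean,
                                      cfg.noise_log_intensity_sd, n_noise))
            n_h = n_int / (n_sig * math.sqrt(2 * math.pi))
            n_mz = pool_mz[pick] * (1.0 + rng.normal(0.0, cfg.mz_ppm_sd, n_noise) * 1e-6)
            m, t, y, feat = _profile_rows(scans, n_rt, n_sig, n_h, n_mz, rng,
                                          cfg.scan_noise_sd, span=2.5)
            mz_parts.append(m)
            rt_parts.append(t)
            y_parts.append(y)
            if cfg.with_im:
                im_parts.append(rng.uniform(*cfg.im_range, n_noise)[feat])
            if cfg.faims_cvs:
                cv_parts.append(faims_of_noise[pick][feat])

        peak_maps[run] = RunPeakMap(
            run_id=run,
            mz=np.concatenate(mz_parts),
            rt=np.concatenate(rt_parts),
            intensity=np.concatenate(y_parts),
            im=np.concatenate(im_parts) if cfg.with_im else None,
            faims_cv=np.concatenate(cv_parts) if cfg.faims_cvs else None,
        )

        # MS/MS sampling: logistic probability in log intensity
        z = (np.log(inten) - cfg.msms_detect_mid) / cfg.msms_detect_scale
        p_detect = cfg.msms_detect_max / (1.0 + np.exp(-z))
        detected = rng.uniform(size=idx.size) < p_detect
        for pos, ion_id in enumerate(idx):
            planted_rows.append({
                "run_id": run, "ion_id": int(ion_id), "apex_rt": float(apex[pos]),
                "intensity": float(inten[pos]), "detected": bool(detected[pos]),
            })
            if detected[pos]:
                psms.append(PsmRecord(
                    ion=IonKey(ions.at[ion_id, "sequence"], "", int(charge_arr[ion_id])),
                    run_id=run,
                    calibrated_mz=float(run_mz[pos]),
                    rt=float(apex[pos] + rng.normal(0.0, cfg.msms_rt_error_sd)),
                    im=float(im_arr[ion_id]) if cfg.with_im else None,
                    faims_cv=float(faims_of_ion[ion_id]) if cfg.faims_cvs else None,
                    protein_ids=(ions.at[ion_id, "protein"],),
                    probability=0.99,
                ))

    planted = pd.DataFrame(planted_rows,
                           columns=["run_id", "ion_id", "apex_rt", "intensity",
                                    "detected"])
    psms.sort(key=lambda r: (r.run_id, r.ion))
    return SimulatedExperiment(
        config=cfg, peak_maps=peak_maps, psms=psms, ions=ions,
        planted=planted, run_conditions=conditions,
    )


def evaluate_transfers(
    rows: list[QuantRow],
    sim: SimulatedExperiment,
) -> dict:
    """Ground-truth metrics for a set of quantification rows.

    ``false_transfer_fraction``: among MBR rows, the fraction whose ion was
    never planted in the acceptor run.  ``species_fpr``: unique yeast
    peptides observed in human-only runs divided by all unique yeast
    peptides observed (the two-organism benchmark's false positive rate).
    ``coverage``: per human-only run, human peptides in the run divided by
    all human peptides observed.
    """
    planted = sim.planted_set
    species_of_seq = dict(zip(sim.ions["sequence"], sim.ions["species"]))

    mbr_rows = [r for r in rows if r.source == "MBR"]
    n_false = sum(1 for r in mbr_rows if (r.run_id, r.ion) not in planted)
    metrics = {
        "n_rows": len(rows),
        "n_transfers": len(mbr_rows),
        "n_false_transfers": n_false,
        "false_transfer_fraction": n_false / len(mbr_rows) if mbr_rows else 0.0,
    }

    if sim.config.design == "two_organism":
        h_runs = {r for r, c in sim.run_conditions.items() if c == "H"}
        yeast_all = {r.ion.sequence for r in rows
                     if species_of_seq.get(r.ion.sequence) == "yeast"}
        yeast_in_h = {r.ion.sequence for r in rows
                      if r.run_id in h_runs
                      and species_of_seq.get(r.ion.sequence) == "yeast"}
        metrics["species_fpr"] = len(yeast_in_h) / len(yeast_all) if yeast_all else 0.0
        human_all = {r.ion.sequence for r in rows
                     if species_of_seq.get(r.ion.sequence) == "human"}
        cov = []
        for run in sorted(h_runs):
            in_run = {r.ion.sequence for r in rows if r.run_id == run
                      and species_of_seq.get(r.ion.sequence) == "human"}
            cov.append(len(in_run) / len(human_all) if human_all else 0.0)
        metrics["mean_h_run_coverage"] = float(np.mean(cov)) if cov else 0.0
    return metrics


def species_log2_ratios(
    prot_table: pd.DataFrame,
    sim: SimulatedExperiment,
) -> dict[str, float]:
    """Median per-species estimated log2(A/B) protein ratio (3-species design)."""
    a_runs = [r for r, c in sim.run_conditions.items() if c == "A"]
    b_runs = [r for r, c in sim.run_conditions.items() if c == "B"]
    species_of_protein = dict(zip(sim.ions["protein"], sim.ions["species"]))
    out: dict[str, list[float]] = {}
    for row in prot_table.itertuples(index=False):
        a = np.nanmean([getattr(row, f"intensity_{r}") for r in a_runs])
        b = np.nanmean([getattr(row, f"intensity_{r}") for r in b_runs])
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
            continue
        sp = species_of_protein.get(row.protein)
        out.setdefault(sp, []).append(math.log2(a / b))
    return {sp: float(np.median(v)) for sp, v in out.items() if v}
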