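"""End-to-end quantification: trace, normalize, transfer, filter, roll up.

Stage order: MS/MS-seeded feature tracing -> normalization fit (on MS/MS
ions only) -> pairwise run correlations -> donor selection -> target and
decoy transfers -> discriminant training on already-identified transfers ->
mixture model / EM on the remaining transfers -> ion-, peptide- and
protein-level transfer FDR filters -> merge of MS/MS and accepted
transferred rows -> MaxLFQ protein intensities -> reports.

FAIMS data are detected automatically from the peak maps' compensation
voltage column; tracing and transfer then operate within each voltage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fdr as _fdr
from . import io as _io
from . import maxlfq as _maxlfq
from . import normalize as _normalize
from . import transfer as _transfer
from .config import PipelineConfig
from .model import MBR, MSMS, IonKey, PsmRecord, QuantRow, RunPeakMap, partition_by_cv
from .tracing import TraceParams, quantify_feature

log = logging.getLogger(__name__)


@dataclasses.dataclass
class MbrCandidates:
    """All transfer candidates of one study plus fitted models."""

    targets: list[_transfer.TransferCandidate]   # type 1, deduplicated, scored
    decoys: list[_transfer.TransferCandidate]    # type -1, deduplicated, scored
    lda: _fdr.LdaModel | None
    mixture: _fdr.MixtureFit | None
    posteriors: np.ndarray  # aligned with targets; all 1.0 in fallback mode
    fallback: bool


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    run_ids: list[str]
    msms_rows: list[QuantRow]
    rows: list[QuantRow]              # MSMS + accepted MBR, normalized
    candidates: MbrCandidates | None
    normalization: _normalize.NormalizationModel | None
    protein_table: pd.DataFrame
    counts: dict


def _trace_params(cfg: PipelineConfig) -> TraceParams:
    return TraceParams(
        ppm_tolerance=cfg.ppm_tolerance,
        boundary_fraction=cfg.boundary_fraction,
        smooth_window=cfg.smooth_window,
        smooth_polyorder=cfg.smooth_polyorder,
        resample_interval=cfg.resample_interval,
        rt_pad=cfg.rt_pad,
        min_rt_halfwidth=cfg.min_rt_halfwidth,
        min_im_halfwidth=cfg.min_im_halfwidth,
    )


def _trace_msms(
    layers: dict,
    psms: list[PsmRecord],
    cfg: PipelineConfig,
    params: TraceParams,
) -> dict[tuple[float | None, str], dict[IonKey, _transfer.IonObservation]]:
    """Trace every PSM's feature; keep the strongest trace per (cv, run, ion)."""
    summaries: dict = {}
    features: dict = {}
    for psm in psms:
        cv = psm.faims_cv
        key = (cv, psm.run_id)
        pmap = layers.get(key)
        if pmap is None:
            continue
        im_lo = im_hi = None
        if psm.im is not None and pmap.im is not None:
            im_lo, im_hi = psm.im - cfg.mbr_im_window, psm.im + cfg.mbr_im_window
        feat = quantify_feature(
            pmap, psm.calibrated_mz, psm.ion.charge,
            psm.rt - cfg.msms_rt_halfwidth, psm.rt + cfg.msms_rt_halfwidth,
            im_lo=im_lo, im_hi=im_hi, apex_hint=psm.rt, params=params,
        )
        if feat is None:
            continue
        cur = features.get((key, psm.ion))
        if cur is None or feat.intensity > cur[0].intensity:
            features[(key, psm.ion)] = (feat, psm)
    for (key, ion), (feat, psm) in features.items():
        summaries.setdefault(key, {})[ion] = (feat, psm)
    return summaries


def run_pipeline(
    peak_maps: dict[str, RunPeakMap],
    psms: list[PsmRecord],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full quantification pipeline in memory."""
    cfg = config or PipelineConfig()
    params = _trace_params(cfg)
    run_ids = sorted(peak_maps)
    counts: dict = {"runs": len(run_ids), "psms": len(psms)}

    # ---- FAIMS partitioning -------------------------------------------
    layers: dict[tuple[float | None, str], RunPeakMap] = {}
    for run in run_ids:
        for cv, part in partition_by_cv(peak_maps[run]).items():
            layers[(cv, run)] = part
    cvs = sorted({cv for cv, _ in layers}, key=lambda v: (v is None, v))
    counts["faims_voltages"] = len([c for c in cvs if c is not None])

    # ---- stage 1: MS/MS-seeded tracing --------------------------------
    traced = _trace_msms(layers, psms, cfg, params)
    msms_rows: list[QuantRow] = []
    for key in sorted(traced, key=lambda k: (str(k[0]), k[1])):
        for ion in sorted(traced[key]):
            feat, psm = traced[key][ion]
            msms_rows.append(QuantRow(
                run_id=key[1], ion=ion, feature=feat, source=MSMS,
                protein_ids=psm.protein_ids, intensity=feat.intensity,
            ))
    counts["msms_features"] = len(msms_rows)

    # ---- stage 2: normalization (fit on MS/MS ions only) ---------------
    norm_model = None
    if cfg.normalize and len(run_ids) >= 2 and msms_rows:
        table = pd.DataFrame({
            "run_id": [r.run_id for r in msms_rows],
            "ion": [r.ion for r in msms_rows],
            "mz": [r.feature.mono_mz for r in msms_rows],
            "intensity": [r.intensity for r in msms_rows],
        })
        norm_model = _normalize.fit_normalization(table)
        msms_rows = _normalize.apply_normalization(norm_model, msms_rows)

    # ---- stages 3-7: MBR ------------------------------------------------
    candidates = None
    accepted_rows: list[QuantRow] = []
    if cfg.mbr and len(run_ids) >= 2:
        candidates = _run_mbr(layers, traced, cfg, params, norm_model, counts)
        accepted_rows = _select_transfers(
            candidates, cfg.ion_fdr, cfg.peptide_fdr, cfg.protein_fdr, norm_model)
        counts["accepted_transfers"] = len(accepted_rows)
    elif cfg.mbr:
        log.warning("MBR requested but only one run present; skipping")

    rows = msms_rows + accepted_rows

    # ---- stage 8: MaxLFQ protein intensities ----------------------------
    ion_long = pd.DataFrame({
        "protein": [r.protein_ids[0] if r.protein_ids else "" for r in rows],
        "run_id": [r.run_id for r in rows],
        "ion": [r.ion for r in rows],
        "intensity": [r.intensity for r in rows],
    })
    prot = _maxlfq.protein_table(ion_long, run_ids, min_ions=cfg.min_ions) \
        if len(rows) else pd.DataFrame(
            columns=["protein", "n_ions", "n_components"]
            + [f"intensity_{r}" for r in run_ids])
    counts["rows"] = len(rows)
    counts["proteins_quantified"] = len(prot)

    return PipelineResult(
        config=cfg, run_ids=run_ids, msms_rows=msms_rows, rows=rows,
        candidates=candidates, normalization=norm_model,
        protein_table=prot, counts=counts,
    )


def _run_mbr(layers, traced, cfg, params, norm_model, counts) -> MbrCandidates:
    """Stages 3-7: correlations, donor selection, transfers, LDA, mixture."""
    all_cands: list[_transfer.TransferCandidate] = []
    n_attempted = 0

    cv_groups: dict[float | None, list[str]] = {}
    for cv, run in layers:
        cv_groups.setdefault(cv, []).append(run)

    for cv in sorted(cv_groups, key=lambda v: (v is None, v)):
        runs = sorted(cv_groups[cv])
        if len(runs) < 2:
            continue
        summaries: dict[str, dict] = {}
        for run in runs:
            obs = {}
            for ion, (feat, psm) in traced.get((cv, run), {}).items():
                inten = feat.intensity
                if norm_model is not None:
                    inten *= norm_model.factor(run)
                obs[ion] = _transfer.IonObservation(
                    rt=feat.rt_apex, intensity=inten,
                    calibrated_mz=psm.calibrated_mz,
                    protein_ids=psm.protein_ids, im=feat.im_center,
                )
            summaries[run] = obs

        corrs = []
        for i, a in enumerate(runs):
            for b in runs[i + 1:]:
                corrs.append(_transfer.compute_pair_correlation(
                    summaries[a], summaries[b], donor_id=a, acceptor_id=b))

        for acceptor in runs:
            donors = _transfer.select_donor_runs(
                acceptor, corrs, top_n=cfg.mbr_top_runs, min_corr=cfg.mbr_min_corr)
            if not donors:
                continue
            acc_map = layers[(cv, acceptor)]
            acc_ions = set(summaries[acceptor])
            type2_done: set[IonKey] = set()
            for donor in donors:
                rt_pairing = _transfer.RtPairing.build(
                    summaries[donor], summaries[acceptor], "rt")
                if rt_pairing is None or rt_pairing.n == 0:
                    continue
                im_pairing = _transfer.RtPairing.build(
                    summaries[donor], summaries[acceptor], "im")
                if im_pairing is not None and im_pairing.n == 0:
                    im_pairing = None
                for ion in sorted(summaries[donor]):
                    is_type2 = ion in acc_ions
                    if is_type2 and ion in type2_done:
                        continue  # training transfers: one donor suffices
                    obs = summaries[donor][ion]
                    n_attempted += 1
                    target, decoy = _transfer.transfer_ion(
                        ion, obs, donor, acc_map, rt_pairing, im_pairing,
                        acc_ions, params, tau_rt=cfg.mbr_rt_window,
                        tau_im=cfg.mbr_im_window, kl_floor=cfg.kl_floor,
                        lambda_coef=cfg.lambda_coef,
                        rt_diff_reference=cfg.rt_diff_reference, cv=cv,
                    )
                    if is_type2:
                        type2_done.add(ion)
                    if target is not None:
                        all_cands.append(target)
                    if decoy is not None:
                        all_cands.append(decoy)

    counts["transfer_attempts"] = n_attempted
    counts["transfer_candidates"] = len(all_cands)
    with_im = any(c.scores.im_diff_sqrt is not None for c in all_cands)

    def vectors(types: tuple[int, ...]) -> np.ndarray:
        return np.array([c.scores.vector(with_im) for c in all_cands
                         if c.ion_type in types]).reshape(-1, 4 + int(with_im))

    X2, Xm2 = vectors((2,)), vectors((-2,))
    counts["type2"] = len(X2)
    counts["type_minus2"] = len(Xm2)

    lda = None
    fallback = False
    try:
        lda = _fdr.train_lda(X2, Xm2, min_class=cfg.lda_min_class)
    except _fdr.FdrModelError as exc:
        log.warning("cannot train transfer discriminant (%s); accepting all "
                    "transfers with posterior 1.0", exc)
        fallback = True

    if not fallback:
        for c in all_cands:
            c.composite = float(lda.score(c.scores.vector(with_im))[0])
    else:
        for c in all_cands:
            c.composite = c.scores.log_intensity  # placeholder ordering

    targets = _transfer.deduplicate_transfers(
        [c for c in all_cands if c.is_target], ppm_tolerance=cfg.ppm_tolerance)
    decoys = _transfer.deduplicate_transfers(
        [c for c in all_cands if not c.is_target], ppm_tolerance=cfg.ppm_tolerance)
    type1 = sorted((c for c in targets if c.ion_type == 1),
                   key=lambda c: (c.acceptor_run, c.ion))
    typem1 = [c for c in decoys if c.ion_type == -1]
    counts["type1"] = len(type1)
    counts["type_minus1"] = len(typem1)

    mixture = None
    post = np.ones(len(type1))
    if not fallback and type1:
        s1 = np.array([c.composite for c in type1])
        sm1 = np.array([c.composite for c in typem1])
        try:
            mixture = _fdr.fit_mixture(
                s1, decoy_scores=sm1 if sm1.size else None,
                min_scores=cfg.em_min_scores, max_iter=cfg.em_max_iter,
                tol=cfg.em_tol, kde_null=cfg.kde_null,
                n_true_components=cfg.em_true_components)
            post = _fdr.posteriors(mixture, s1)
        except _fdr.FdrModelError as exc:
            log.warning("mixture model unavailable (%s); accepting all "
                        "transfers with posterior 1.0", exc)
            fallback = True
            post = np.ones(len(type1))

    return MbrCandidates(targets=type1, decoys=typem1, lda=lda,
                         mixture=mixture, posteriors=post, fallback=fallback)


def _select_transfers(
    cands: MbrCandidates,
    ion_alpha: float,
    peptide_alpha: float,
    protein_alpha: float,
    norm_model,
) -> list[QuantRow]:
    """Apply ion -> peptide -> protein transfer FDR filters in sequence."""
    type1 = cands.targets
    if not type1:
        return []
    p = cands.posteriors
    s = np.array([c.composite for c in type1])

    ion_keys = list(range(len(type1)))
    ok_ion = _fdr.accept_at_level(s, p, ion_keys, ion_alpha)
    pep_keys = [c.ion.sequence for c in type1]
    ok_pep = _fdr.accept_at_level(s, p, pep_keys, peptide_alpha)
    prot_keys = [c.leading_protein for c in type1]
    ok_prot = _fdr.accept_at_level(s, p, prot_keys, protein_alpha)

    rows = []
    for idx, c in enumerate(type1):
        if idx not in ok_ion or c.ion.sequence not in ok_pep \
                or c.leading_protein not in ok_prot:
            continue
        inten = c.feature.intensity
        if norm_model is not None:
            inten *= norm_model.factor(c.acceptor_run)
        rows.append(QuantRow(
            run_id=c.acceptor_run, ion=c.ion, feature=c.feature, source=MBR,
            protein_ids=c.protein_ids, intensity=inten,
            transfer_probability=float(p[idx]),
        ))
    rows.sort(key=lambda r: (r.run_id, r.ion))
    return rows


def select_transfers_at(
    result: PipelineResult,
    ion_alpha: float,
    peptide_alpha: float | None = None,
    protein_alpha: float | None = None,
) -> list[QuantRow]:
    """Re-apply the transfer FDR filters at different thresholds without
    recomputing transfers (used to sweep the FDR threshold)."""
    if result.candidates is None:
        return []
    return _select_transfers(
        result.candidates, ion_alpha,
        ion_alpha if peptide_alpha is None else peptide_alpha,
        ion_alpha if protein_alpha is None else protein_alpha,
        result.normalization,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write reports, the serialized config and per-stage counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _io.write_quant_reports(result.rows, result.protein_table, out_dir,
                                    run_ids=result.run_ids)
    result.config.save(out_dir / "config.json")
    (out_dir / "counts.json").write_text(
        json.dumps(result.counts, indent=2, sort_keys=True) + "\n")
    paths["config"] = out_dir / "config.json"
    paths["counts"] = out_dir / "counts.json"
    return paths
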