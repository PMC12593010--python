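"""Stage orchestration: raw recordings to a full results bundle.

The stages run in the order the method prescribes:

1. preprocessing (condition, envelope, time- and amplitude-normalize);
2. iEMG per phase, the weighted group-difference statistic, and the
   screening repeated-measures ANOVA per muscle-leg channel;
3. pooled functional PCA per channel (optionally with continuous
   registration), component retention, and the Welch comparison of
   subject-mean PC scores with Hedges' g;
4. Benjamini-Hochberg FDR adjustment within each comparison family;
5. ICC(3,k) reliability of trial-level scores of every retained component,
   the mixed-model sensitivity analysis, and stepwise discriminant
   screening of subject-level muscle iEMG.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .exceptions import DataError
from .fpca import BasisSpec, fit_basis, register_curves, retain_components, run_fpca
from .gridops import trapezoid_weights
from .iemg import DeltaIemgConfig, PhaseDefinition, delta_iemg_table, integrate_envelope
from .io import EmgRecording, ResultsBundle
from .preprocessing import (
    NormalizedCurve,
    amplitude_normalize,
    condition_raw,
    linear_envelope,
    time_normalize,
)
from .stats import (
    compare_pc_scores,
    adjust_fdr,
    hedges_g,
    icc_3k,
    mixed_model_scores,
    rm_anova_iemg,
    stepwise_discriminant,
)


# ---------------------------------------------------------------------------
# preprocessing stage
# ---------------------------------------------------------------------------

def _cycle_bounds(rec: EmgRecording, events: pd.DataFrame | None) -> tuple[int, int]:
    if events is None:
        return 0, rec.samples.size - 1
    row = events[
        (events["subject"].astype(str) == rec.subject_id)
        & (events["trial"] == rec.trial)
    ]
    if row.empty:
        raise DataError(
            f"no cycle events for subject {rec.subject_id} trial {rec.trial}"
        )
    r = row.iloc[0]
    return int(r["cycle_start"]), int(r["cycle_end"])


def preprocess_recordings(
    recordings: list[EmgRecording],
    config: AnalysisConfig | None = None,
    events: pd.DataFrame | None = None,
) -> list[NormalizedCurve]:
    """Full preprocessing chain to amplitude-normalized cycle curves.

    Raw trials are conditioned and enveloped first; envelope trials whose
    length already equals the grid length are taken as cycle curves
    directly (the synthetic-envelope path), otherwise the cycle segment
    from the events table is resampled onto the grid.  Every
    subject-muscle-leg trial set is then normalized by its maximum.
    """
    cfg = config or AnalysisConfig()
    curves: list[NormalizedCurve] = []
    for rec in recordings:
        if rec.stage == "raw":
            rec = linear_envelope(
                condition_raw(rec, cfg), cfg.envelope_cutoff_hz, cfg.envelope_order
            )
        if rec.stage != "envelope":
            raise DataError(f"unexpected stage {rec.stage!r} in preprocessing")
        if events is None and rec.samples.size == cfg.grid_len:
            curves.append(
                NormalizedCurve(
                    grid=cfg.grid,
                    values=np.clip(rec.samples, 0.0, None),
                    subject_id=rec.subject_id,
                    group=rec.group,
                    leg=rec.leg,
                    muscle=rec.muscle,
                    trial=rec.trial,
                )
            )
        else:
            start, end = _cycle_bounds(rec, events)
            curves.append(time_normalize(rec, start, end, cfg.grid_len))

    out: list[NormalizedCurve] = []
    frame = pd.DataFrame(
        {"i": range(len(curves)),
         "key": [(c.subject_id, c.group, c.leg, c.muscle) for c in curves]}
    )
    for _, g in frame.groupby("key"):
        subset = [curves[i] for i in g["i"]]
        out.extend(amplitude_normalize(subset, cfg.max_norm_trials))
    return out


# ---------------------------------------------------------------------------
# iEMG stage
# ---------------------------------------------------------------------------

def compute_iemg(
    curves: list[NormalizedCurve],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    cfg = config or AnalysisConfig()
    phases = PhaseDefinition(cfg.phase_boundaries)
    rows = []
    for c in curves:
        for phase, v in integrate_envelope(c, phases).items():
            rows.append(
                {"subject": c.subject_id, "group": c.group, "leg": c.leg,
                 "muscle": c.muscle, "trial": c.trial, "phase": phase, "iemg": v}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FPCA stage
# ---------------------------------------------------------------------------

def fpca_by_channel(
    curves: list[NormalizedCurve],
    config: AnalysisConfig | None = None,
) -> dict:
    """Pooled (both groups together) FPCA per (muscle, leg) channel."""
    cfg = config or AnalysisConfig()
    spec = BasisSpec(order=cfg.basis_order, period=100.0, lam=cfg.smoothing)
    results: dict = {}
    keys = sorted({(c.muscle, c.leg) for c in curves})
    for muscle, leg in keys:
        subset = [c for c in curves if (c.muscle, c.leg) == (muscle, leg)]
        ds = fit_basis(subset, spec)
        if cfg.register:
            ds, _ = register_curves(ds)
        res = run_fpca(ds)
        retain_components(res, cfg.ev_floor, cfg.cum_floor)
        results[(muscle, leg)] = res
    return results


def trial_scores_frame(result) -> pd.DataFrame:
    """Trial-level retained-component scores with provenance columns."""
    rows = []
    K = result.n_retained or result.scores.shape[1]
    for (subj, group, leg, muscle, trial), sc in zip(
        result.provenance, result.scores
    ):
        for k in range(K):
            rows.append(
                {"subject": subj, "group": group, "leg": leg, "muscle": muscle,
                 "trial": trial, "pc": k + 1, "score": sc[k]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(
    recordings: list[EmgRecording],
    config: AnalysisConfig | None = None,
    events: pd.DataFrame | None = None,
) -> ResultsBundle:
    """Execute every stage and assemble the results bundle."""
    cfg = config or AnalysisConfig()
    curves = preprocess_recordings(recordings, cfg, events)
    iemg = compute_iemg(curves, cfg)
    delta = delta_iemg_table(
        iemg, DeltaIemgConfig(cfg.omega_elite, cfg.omega_sub)
    )

    # --- iEMG screening per channel (full-cycle values) --------------------
    iemg_rows = []
    full = iemg[iemg["phase"] == "full"]
    for (muscle, leg), g in full.groupby(["muscle", "leg"]):
        an = rm_anova_iemg(g, cfg.alpha)
        subj = g.groupby(["group", "subject"])["iemg"].mean()
        es = hedges_g(
            subj.loc["elite"].to_numpy(), subj.loc["sub_elite"].to_numpy(),
            alpha=cfg.alpha,
        )
        iemg_rows.append(
            {"family": "iemg", "muscle": muscle, "leg": leg, "pc": np.nan,
             "F": an.F, "df1": an.df[0], "df2": an.df[1], "p": an.p,
             "partial_eta_sq": an.partial_eta_sq,
             "eta_ci_low": an.eta_ci[0], "eta_ci_high": an.eta_ci[1],
             "shapiro_p": an.shapiro_p, "levene_p": an.levene_p,
             "hedges_g": es.value, "g_ci_low": es.ci[0], "g_ci_high": es.ci[1],
             "effect_label": es.label}
        )

    # --- pooled FPCA and PC-score comparison -------------------------------
    fpca_results = fpca_by_channel(curves, cfg)
    pc_rows = []
    reliability_rows = []
    for (muscle, leg), res in sorted(fpca_results.items()):
        tscores = trial_scores_frame(res)
        subject_scores = (
            tscores.groupby(["subject", "group", "pc"], as_index=False)["score"]
            .mean()
        )
        cmp_rows = compare_pc_scores(subject_scores, cfg.alpha)
        for _, r in cmp_rows.iterrows():
            pc = int(r["pc"])
            mm = mixed_model_scores(
                tscores[tscores["pc"] == pc], cfg.alpha
            )
            row = {"family": "pc", "muscle": muscle, "leg": leg, **r.to_dict(),
                   "mm_subject_var": mm.subject_var,
                   "mm_residual_var": mm.residual_var,
                   "mm_group_effect": mm.group_effect, "mm_group_p": mm.group_p}
            pc_rows.append(row)
            mat = (
                tscores[tscores["pc"] == pc]
                .pivot(index="subject", columns="trial", values="score")
                .to_numpy()
            )
            # reliability on the uncentered projection int xi_k x dt: same
            # ICC and SEM, but a ratio scale so the CV is meaningful
            w_quad = trapezoid_weights(res.grid)
            offset = float(np.sum(w_quad * res.eigenfunctions[pc - 1] * res.mean))
            icc = icc_3k(mat + offset, cfg.alpha)
            reliability_rows.append(
                {"muscle": muscle, "leg": leg, "pc": pc, "k": icc.k,
                 "icc_3k": icc.icc, "ci_low": icc.ci[0], "ci_high": icc.ci[1],
                 "sem": icc.sem, "cv_pct": icc.cv, "negative": icc.negative}
            )

    # --- FDR within each family --------------------------------------------
    stats = pd.concat(
        [pd.DataFrame(iemg_rows), pd.DataFrame(pc_rows)], ignore_index=True
    )
    stats["p_adj"] = np.nan
    for fam in stats["family"].unique():
        mask = stats["family"] == fam
        stats.loc[mask, "p_adj"] = adjust_fdr(
            stats.loc[mask, "p"].to_numpy(), cfg.fdr_method
        )
    stats["significant"] = stats["p_adj"] < cfg.alpha

    # --- stepwise discriminant screening on subject-level muscle iEMG ------
    feat = (
        full.groupby(["subject", "group", "muscle", "leg"], as_index=False)["iemg"]
        .mean()
        .assign(channel=lambda d: d["muscle"] + "|" + d["leg"])
        .pivot(index=["subject", "group"], columns="channel", values="iemg")
    )
    labels = feat.index.get_level_values("group").to_numpy()
    selected, trace = stepwise_discriminant(
        feat.reset_index(drop=True), labels, cfg.f_enter, cfg.f_remove
    )

    return ResultsBundle(
        iemg=iemg,
        delta_iemg=delta,
        fpca=fpca_results,
        stats=stats,
        reliability=pd.DataFrame(reliability_rows),
        config=cfg.to_dict(),
        extras={"discriminant_selected": selected, "discriminant_trace": trace},
    )
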