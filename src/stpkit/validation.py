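"""End-to-end validation harness over the synthetic study conditions.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and scores the result against ground truth or against an
independent oracle (ODE integration for the release recursion, full
enumeration for the exact rank-sum test, the direct step-up formula for the
BH adjustment).  The oracles here are deliberately written against the
underlying mathematics, not the implementation they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import (
    Blob,
    EPSPKinetics,
    IntrinsicPopulationSpec,
    ReleaseModelParams,
    StimProtocol,
    SyntheticVolumeSpec,
    background_threshold,
    compute_metrics,
    cross_validate,
    extract_connection,
    fdr_adjust,
    fit_classifier,
    harmonize_features,
    lipofuscin_mask,
    render_sweeps,
    simulate_cohort,
    simulate_connection,
    simulate_intrinsic_features,
    simulate_mfish_volume,
    simulate_release_train,
    two_way_rm_anova,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------- release
def _release_train_ode(U, tau_rec, tau_facil, A, pulse_times):
    """Independent oracle: integrate the two-state ODE between spikes."""
    u, R = U, 1.0
    amps = []
    for k, t in enumerate(pulse_times):
        amps.append(A * u * R)
        if k + 1 == len(pulse_times):
            break
        dt = pulse_times[k + 1] - t
        R_post = R * (1.0 - u)
        u_post = U + u * (1.0 - U)
        sol = solve_ivp(
            lambda _, y: [(1.0 - y[0]) / tau_rec, (U - y[1]) / tau_facil],
            (0.0, dt), [R_post, u_post], rtol=1e-11, atol=1e-13,
        )
        R, u = sol.y[0, -1], sol.y[1, -1]
    return np.array(amps)


def release_model_oracle_error(n_draws: int = 100, seed: int = 0) -> float:
    """Max relative error of the recursion vs ODE integration."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        U = rng.uniform(0.05, 0.95)
        tau_rec = rng.uniform(0.02, 2.0)
        tau_facil = rng.uniform(0.005, 2.0)
        freq = rng.choice([10.0, 20.0, 50.0, 100.0])
        delay = rng.choice([0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0])
        t = StimProtocol(frequency=freq, recovery_delay=delay).pulse_times()
        params = ReleaseModelParams(U=U, tau_rec=tau_rec, tau_facil=tau_facil, A=2.0)
        rec = simulate_release_train(params, t)
        ode = _release_train_ode(U, tau_rec, tau_facil, 2.0, t)
        worst = max(worst, float(np.max(np.abs(rec - ode) / ode)))
    return worst


# ------------------------------------------------------------- extraction
def epsp_recovery_errors(
    n_connections: int = 200, seed: int = 0
) -> dict[str, float]:
    """Median absolute first-EPSP amplitude and decay-tau recovery errors.

    Connections span 0.2–5 mV first-pulse amplitudes with trace noise up to
    0.3 mV, rendered at 20 Hz so the decay-fit window is unconstrained.
    """
    rng = np.random.default_rng(seed)
    amp_err, tau_err = [], []
    protocol = StimProtocol(frequency=20.0, n_sweeps=10)
    for i in range(n_connections):
        first_amp = np.exp(rng.uniform(np.log(0.2), np.log(5.0)))
        U = rng.uniform(0.3, 0.6)
        A = first_amp / U
        params = ReleaseModelParams(
            U=U, tau_rec=rng.uniform(0.3, 0.8), tau_facil=rng.uniform(0.005, 0.05),
            A=A, noise_sd=rng.uniform(0.0, 0.3),
        )
        kin = EPSPKinetics(
            tau_rise=rng.uniform(1.5, 3.0),
            tau_decay=rng.uniform(12.0, 30.0),
            onset_delay=rng.uniform(0.8, 2.5),
        )
        sweeps, truth = simulate_connection(
            params, protocol, kin, seed=int(rng.integers(0, 2**31 - 1))
        )
        rec = extract_connection(sweeps, connection_id=f"c{i}")
        f = rec.first_epsp
        amp_err.append(abs(f.amplitude - truth.mean_amplitudes[0]) / truth.mean_amplitudes[0])
        if np.isfinite(f.decay_tau):
            tau_err.append(abs(f.decay_tau - kin.tau_decay) / kin.tau_decay)
    return dict(
        median_amplitude_error=float(np.median(amp_err)),
        median_decay_tau_error=float(np.median(tau_err)),
        n=n_connections,
    )


# ---------------------------------------------------------------- metrics
def stp_call_accuracy(
    n_depressing: int = 50, n_facilitating: int = 50, seed: int = 0
) -> dict[str, float]:
    """Fraction of correct depressing/facilitating calls by 50 Hz PPR."""
    cohort = simulate_cohort(
        n_depressing=n_depressing, n_facilitating=n_facilitating,
        frequency=50.0, noise_sd_frac=0.1, n_sweeps=10, seed=seed,
    )
    calls = [compute_metrics(r).dynamics_call for r in cohort.records]
    truth = cohort.truth["regime"].tolist()
    acc = float(np.mean([c == t for c, t in zip(calls, truth)]))
    return dict(accuracy=acc, n=len(calls))


# ------------------------------------------------------------- classifier
def classifier_label_recovery(seed: int = 0) -> dict[str, float]:
    """End-to-end harmonize → fit → calibrate → band label recovery,
    plus a label-permutation CV null."""
    spec = IntrinsicPopulationSpec(
        n_per_class=200, missing_rate=0.05, protocol_shift={"spike_width": 3.0}
    )
    tab = simulate_intrinsic_features(spec, seed=seed)
    harm = harmonize_features(tab)
    clf = fit_classifier(tab, harm.retained)
    preds = clf.predict(tab)
    labels = np.array([p.label for p in preds])
    truth = tab["subclass"].to_numpy()
    outside = labels != "uncertain"
    recovery = float(np.mean(labels[outside] == truth[outside]))

    null_spec = IntrinsicPopulationSpec(n_per_class=1000)
    null_tab = simulate_intrinsic_features(null_spec, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    null_tab = null_tab.assign(subclass=rng.permutation(null_tab["subclass"].to_numpy()))
    feats = [c for c in null_tab.columns if c not in ("protocol", "subclass")]
    null_rep = cross_validate(null_tab, feats, seed=seed)
    return dict(
        label_recovery=recovery,
        uncertain_fraction=float(1.0 - outside.mean()),
        permutation_null_accuracy=float(null_rep.accuracy),
        n=len(tab),
    )


def harmonization_filter_performance(
    n_replicates: int = 100, seed: int = 0
) -> dict[str, float]:
    """Exclusion/retention performance of the protocol-variance filter.

    Per replicate, three features carry a strong injected protocol shift
    (eta² far above the 5% threshold); the rest are protocol-independent.
    """
    rng = np.random.default_rng(seed)
    shifted = ("sag", "spike_width", "membrane_tau")
    ok = 0
    false_excl = false_ret = 0
    for _ in range(n_replicates):
        spec = IntrinsicPopulationSpec(
            n_per_class=300,
            protocol_shift={f: 1.5 for f in shifted},
        )
        tab = simulate_intrinsic_features(spec, seed=int(rng.integers(0, 2**31 - 1)))
        res = harmonize_features(tab)
        excluded = set(spec.feature_names) - set(res.retained)
        false_excl += len(excluded - set(shifted))
        false_ret += len(set(shifted) & set(res.retained))
        if excluded == set(shifted):
            ok += 1
    return dict(
        replicate_success_rate=ok / n_replicates,
        false_exclusions=false_excl,
        false_retentions=false_ret,
        n=n_replicates,
    )


# ------------------------------------------------------------------ mfish
def mfish_mask_scores(seed: int = 0) -> dict[str, float]:
    """Lipofuscin-mask recall/precision and background-threshold accuracy."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    blobs = [
        Blob(tuple(c), float(r), 420.0)
        for c, r in zip(
            rng.uniform((3, 8, 8), (13, 56, 56), size=(6, 3)),
            rng.uniform(1.5, 3.5, size=6),
        )
    ]
    spots = [
        Blob(tuple(c), float(r), 420.0, channel=int(ch))
        for c, r, ch in zip(
            rng.uniform((3, 8, 8), (13, 120, 120), size=(12, 3)),
            rng.uniform(1.0, 2.5, size=12),
            rng.integers(0, 3, size=12),
        )
    ]
    spec = SyntheticVolumeSpec(
        shape=(16, 128, 128), lipofuscin_blobs=blobs, spots=spots
    )
    stack, truth = simulate_mfish_volume(spec, seed=seed)
    noncell = np.ones(stack.shape[1:], bool)
    models = [background_threshold(stack[c], noncell) for c in range(stack.shape[0])]
    sigma_hwhm = 10.0 * np.sqrt(2 * np.log(2))
    analytic = 100.0 + 3.0 * sigma_hwhm
    thr_err = max(abs(m.threshold - analytic) / analytic for m in models)

    mask = lipofuscin_mask(stack, np.array([m.threshold for m in models]))
    blob_mask = truth.lipofuscin_mask
    recall = float((mask & blob_mask).sum() / blob_mask.sum())
    struct = ndimage.generate_binary_structure(3, 1)
    ring = ndimage.binary_dilation(blob_mask, struct, iterations=2) & ~blob_mask
    considered = mask & ~ring
    precision = float((considered & blob_mask).sum() / considered.sum())
    spot_overlap = int(sum((mask & s).sum() for s in truth.spot_masks))
    return dict(
        recall=recall,
        precision=precision,
        threshold_relative_error=float(thr_err),
        spot_overlap_voxels=spot_overlap,
        n=int(blob_mask.sum()),
    )


# ------------------------------------------------------------------ stats
def _ranksum_enumeration_p(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    all_ranks = np.arange(1, n + m + 1)
    us = np.array(
        [all_ranks[list(idx)].sum() - n * (n + 1) / 2
         for idx in combinations(range(n + m), n)]
    )
    total = comb(n + m, n)
    return min(1.0, 2.0 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total)


def _bh_direct(p):
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p)
    adj = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def stats_oracle_errors(
    n_bh_vectors: int = 1000, n_anova_sims: int = 400, seed: int = 0
) -> dict[str, float]:
    """Agreement with enumeration/step-up oracles and rm-ANOVA type-I rate."""
    rng = np.random.default_rng(seed)
    ranksum_err = 0.0
    for nx in range(1, 7):
        for ny in range(1, 7):
            x = rng.normal(size=nx)
            y = rng.normal(0.5, size=ny)
            got = wilcoxon_rank_sum(x, y).p_value
            ranksum_err = max(ranksum_err, abs(got - _ranksum_enumeration_p(x, y)))

    bh_err = 0.0
    for _ in range(n_bh_vectors):
        p = rng.random(int(rng.integers(1, 40)))
        bh_err = max(bh_err, float(np.max(np.abs(fdr_adjust(p) - _bh_direct(p)))))

    rejections = 0
    n_sub, n_levels = 8, 4
    for _ in range(n_anova_sims):
        rows = []
        for group in ("acute", "culture"):
            for s in range(n_sub):
                base = rng.normal(0, 1.0)
                for lv in range(n_levels):
                    rows.append(
                        dict(subject=f"{group}{s}", prep=group, delay=f"d{lv}",
                             y=base + rng.normal(0, 0.5))
                    )
        res = two_way_rm_anova(pd.DataFrame(rows), "y", "delay", "subject", "prep")
        p_between = res.loc[res.effect == "between", "p"].iloc[0]
        rejections += int(p_between < 0.05)
    return dict(
        ranksum_enumeration_max_abs_error=float(ranksum_err),
        bh_stepup_max_abs_error=float(bh_err),
        rm_anova_type1_rate=rejections / n_anova_sims,
        n=n_anova_sims,
    )
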