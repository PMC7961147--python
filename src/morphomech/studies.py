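"""End-to-end synthetic studies exercising the full analysis chain.

Each function builds its own data from the generators in
:mod:`morphomech.synthetic` under the documented study conditions, runs the
relevant models, and returns the summary quantities.  They are shared by the
test suite, the acceptance script, and the pipeline runner so that every
reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aberrance, classifier, mechanics, som, synthetic, yapnet


def yap_prediction_study(
    seed: int = 0, n_per_archetype: int = 100, explainable_variance: float = 0.65
) -> dict:
    """Morphology -> YAP/TAZ predictability on a coupled population.

    Generates 4 x ``n_per_archetype`` cells, calibrates the coupling noise so
    the ground-truth explainable variance matches the target, Grubbs-screens
    the training targets, trains the 4-hidden-neuron Bayesian-regularized
    net on 75% of the cells, and reports held-out R^2.
    """
    pop = synthetic.generate_population(n_per_archetype=n_per_archetype, seed=seed)
    base = synthetic.CouplingSpec()
    noise = synthetic.noise_sd_for_explainable_variance(pop, base, explainable_variance)
    coupling = synthetic.CouplingSpec(noise_sd=noise)
    table, info = synthetic.assign_yap(pop, coupling, seed=seed + 1)

    tr, te = yapnet.split_data(len(table), 0.75, seed=seed + 2)
    y = table["yap_ratio"].to_numpy()
    keep = aberrance.grubbs_filter(y[tr]).kept
    # indices of kept training cells (Grubbs removes at most the extreme point)
    kept_mask = np.isin(y[tr], keep)
    X = table[synthetic.FEATURE_COLUMNS]
    model = yapnet.train_bayesian_mlp(X.iloc[tr[kept_mask]], y[tr][kept_mask], seed=seed + 3)
    res_tr = yapnet.evaluate(model, X.iloc[tr], y[tr])
    res_te = yapnet.evaluate(model, X.iloc[te], y[te])
    return {
        "model": model,
        "table": table,
        "train_idx": tr,
        "test_idx": te,
        "r2_train": res_tr.r2,
        "r2_test": res_te.r2,
        "sigma_train": float(res_tr.errors.std(ddof=1)),
        "explainable_variance": info["explainable_variance"],
    }


def som_study(seed: int = 0, n_per_archetype: int = 261) -> dict:
    """2x2 SOM on the heterogeneous 4-archetype population (~1000 cells)."""
    pop = synthetic.generate_population(n_per_archetype=n_per_archetype, seed=seed)
    model = som.train_som(pop, grid=(2, 2), seed=seed + 1)
    assign = som.assign_clusters(model, pop)
    counts = np.bincount(assign, minlength=model.n_units + 1)[1:]
    # majority-archetype purity over all cells
    purity = (
        pd.crosstab(assign, pop["group"]).max(axis=1).sum() / len(pop)
    )
    return {
        "model": model,
        "assignments": assign,
        "n_nonempty": int((counts > 0).sum()),
        "purity": float(purity),
        "population": pop,
    }


#: Ground-truth constitutive parameters for the recovery study: a moderately
#: aligned scaffold (35 deg initial spread saturating at 10 deg) with a toe
#: region dominated by fiber nonlinearity.
TRUE_MECH_PARAMS = mechanics.FiberModelParams(
    A=0.1, B=40.0, k_matrix=2.0, sigma0=35.0, sigma_inf=10.0, alpha=20.0, theta0=0.0
)


def mechanics_recovery_study(seed: int = 0, noise_cv: float = 0.02) -> dict:
    """Simulate-and-refit of all seven constitutive parameters.

    Angle histograms at four strains and a toe-region stress-strain curve
    are generated with multiplicative noise of the given CV, then the
    organization parameters and (A, B, k_matrix) are refit.
    """
    true = TRUE_MECH_PARAMS
    hists = synthetic.generate_angle_histograms(
        true, strains=(0.0, 0.03, 0.06, 0.09), noise_cv=noise_cv, seed=seed
    )
    org = mechanics.fit_organization(hists)
    curve_df = synthetic.generate_stress_strain(
        true, strain_max=0.06, n_points=181, noise_cv=noise_cv, seed=seed + 1
    )
    curve = mechanics.StressStrainCurve(
        curve_df["strain"].to_numpy(), curve_df["stress_mpa"].to_numpy()
    )
    fit = mechanics.fit_stress_params(curve, org, toe_region_max_strain=0.06)
    rel = {
        "A": abs(fit.A - true.A) / true.A,
        "B": abs(fit.B - true.B) / true.B,
        "k_matrix": abs(fit.k_matrix - true.k_matrix) / true.k_matrix,
        "sigma0": abs(org.sigma0 - true.sigma0) / true.sigma0,
        "sigma_inf": abs(org.sigma_inf - true.sigma_inf) / true.sigma_inf,
        "alpha": abs(org.alpha - true.alpha) / true.alpha,
    }
    return {
        "org": org,
        "fit": fit,
        "r_squared": fit.r_squared,
        "relative_errors": rel,
        "theta0_abs_error_deg": abs(org.theta0 - true.theta0),
    }


def cue_study(
    seed: int = 0,
    n_control: int = 400,
    n_inhib: int = 150,
    n_agon: int = 100,
    n_eval_per_group: int = 300,
) -> dict:
    """Contractility-cue correction: cue-blind vs 15-input cue-aware model.

    The cue-blind net is trained on control cells only and systematically
    mispredicts drug-treated groups by the planted shifts; adding the cue as
    a 15th input removes the group biases.  Group biases are estimated on an
    independent evaluation population (``n_eval_per_group`` cells per cue
    group) so the mean-error estimates are not dominated by sampling noise.
    """
    coupling = synthetic.CouplingSpec()
    n_total = n_control + n_inhib + n_agon
    n_per = int(np.ceil(n_total / 4))
    pop = synthetic.generate_population(n_per_archetype=n_per, seed=seed).iloc[:n_total]
    pop = pop.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    cue = np.concatenate(
        [np.zeros(n_control, int), -np.ones(n_inhib, int), np.ones(n_agon, int)]
    )
    table, _ = synthetic.assign_yap(pop, coupling, cue=cue, seed=seed + 1)
    X = table[synthetic.FEATURE_COLUMNS]
    y = table["yap_ratio"].to_numpy()

    ctrl = np.flatnonzero(cue == 0)
    tr_c, _ = yapnet.split_data(len(ctrl), 0.75, seed=seed + 2)
    blind = yapnet.train_bayesian_mlp(X.iloc[ctrl[tr_c]], y[ctrl[tr_c]], seed=seed + 3)
    aware = yapnet.train_with_cue(X, cue, y, seed=seed + 5)

    # Independent evaluation population with equal-size cue groups.
    n_eval = 3 * n_eval_per_group
    eva_pop = synthetic.generate_population(
        n_per_archetype=int(np.ceil(n_eval / 4)), seed=seed + 6
    ).iloc[:n_eval]
    eva_cue = np.repeat([0, -1, 1], n_eval_per_group)
    eva, _ = synthetic.assign_yap(eva_pop, coupling, cue=eva_cue, seed=seed + 7)
    eva_group = np.array(["control", "inhibitor", "agonist"])[
        np.select([eva_cue == 0, eva_cue == -1, eva_cue == 1], [0, 1, 2])
    ]
    Xe = eva[synthetic.FEATURE_COLUMNS]
    ye = eva["yap_ratio"].to_numpy()
    res_blind = yapnet.evaluate(blind, Xe, ye, groups=eva_group)
    Xec = np.column_stack([Xe.to_numpy(float), eva_cue.astype(float)])
    res_aware = yapnet.evaluate(aware, Xec, ye, groups=eva_group)
    return {
        "mu_blind": {str(k): v for k, v in res_blind.group_stats["mu"].items()},
        "mu_aware": {str(k): v for k, v in res_aware.group_stats["mu"].items()},
        "r2_aware": res_aware.r2,
    }


def decoupling_study(
    seed: int = 0,
    n_train_pop: int = 1000,
    n_control: int = 1000,
    n_decoupled: int = 300,
    reference_sigma: float = 0.42,
    z_threshold: float = 2.0,
) -> dict:
    """Planted decoupled population vs coupled controls.

    The coupling noise is set to the reference error SD (0.42, the measured
    test-set error SD of the original model) so that coupled control cells
    flag at the nominal two-sided Gaussian tail rate; the decoupled group
    carries the invasive-cell offset (mean 1.52, SD 0.88).
    """
    coupling = synthetic.CouplingSpec(noise_sd=reference_sigma)
    per = int(np.ceil(n_train_pop / 4))
    pop = synthetic.generate_population(n_per_archetype=per, seed=seed).iloc[:n_train_pop]
    table, _ = synthetic.assign_yap(pop, coupling, seed=seed + 1)
    X = table[synthetic.FEATURE_COLUMNS]
    y = table["yap_ratio"].to_numpy()
    tr, _ = yapnet.split_data(len(table), 0.75, seed=seed + 2)
    model = yapnet.train_bayesian_mlp(X.iloc[tr], y[tr], seed=seed + 3)

    per_c = int(np.ceil(n_control / 4))
    ctrl_pop = synthetic.generate_population(n_per_archetype=per_c, seed=seed + 10).iloc[:n_control]
    ctrl, _ = synthetic.assign_yap(ctrl_pop, coupling, seed=seed + 11)
    per_d = int(np.ceil(n_decoupled / 4))
    dec_pop = synthetic.generate_population(n_per_archetype=per_d, seed=seed + 20).iloc[:n_decoupled]
    dec, _ = synthetic.assign_yap(dec_pop, coupling, decoupled=True, seed=seed + 21)

    both = pd.concat([ctrl, dec], ignore_index=True)
    groups = np.array(["control"] * len(ctrl) + ["decoupled"] * len(dec))
    res = yapnet.evaluate(model, both[synthetic.FEATURE_COLUMNS], both["yap_ratio"].to_numpy(), groups=groups)
    flags, frac = aberrance.flag_decoupled(
        res.errors, reference_sigma=reference_sigma, z_threshold=z_threshold, groups=groups
    )
    stats = aberrance.group_error_stats(res.errors, groups, reference_sigma, z_threshold)
    comparison = aberrance.compare_group_errors(res.errors, groups)
    return {
        "model": model,
        "stats": stats,
        "flags": flags,
        "flag_fractions": frac["flag_fraction"].to_dict(),
        "mu_decoupled": float(stats.loc["decoupled", "mu"]),
        "comparison": comparison,
    }


def classifier_study(seed: int = 0, n_per_class: int = 150, decouple: bool = True) -> dict:
    """Train the three classification modes on one two-class dataset."""
    table = synthetic.generate_invasiveness_dataset(
        n_per_class=n_per_class, seed=seed, decouple=decouple
    )
    out: dict = {"table": table}
    for mode in classifier.MODES:
        model = classifier.train_classifier(table, mode=mode, seed=seed)
        X, _ = classifier.select_features(table, mode)
        cm = classifier.confusion(
            model, X[model.test_idx], table["invasive"].to_numpy()[model.test_idx]
        )
        out[mode] = {"accuracy": cm.accuracy, "fnr": cm.false_negative_rate, "model": model}
    return out


def classifier_ordering_study(n_seeds: int = 20, base_seed: int = 0, n_per_class: int = 150) -> dict:
    """Median test accuracies across seeds for the three modes and the
    no-decoupling ("stiff 2D") YAP-only condition."""
    acc = {m: [] for m in classifier.MODES}
    acc_stiff = []
    for k in range(n_seeds):
        s = base_seed + 1000 * k
        res = classifier_study(seed=s, n_per_class=n_per_class, decouple=True)
        for m in classifier.MODES:
            acc[m].append(res[m]["accuracy"])
        stiff = synthetic.generate_invasiveness_dataset(
            n_per_class=n_per_class, seed=s, decouple=False
        )
        model = classifier.train_classifier(stiff, mode="yap", seed=s)
        X, _ = classifier.select_features(stiff, "yap")
        cm = classifier.confusion(
            model, X[model.test_idx], stiff["invasive"].to_numpy()[model.test_idx]
        )
        acc_stiff.append(cm.accuracy)
    return {
        "median_accuracy": {m: float(np.median(acc[m])) for m in classifier.MODES},
        "median_accuracy_yap_stiff2d": float(np.median(acc_stiff)),
        "all": acc,
    }
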