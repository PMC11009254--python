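"""End-to-end experiment orchestration.

One call runs the whole study design on a synthetic cohort:

1. simulate subjects (disease groups with an age confound) and their
   tract profiles, with bundle missingness;
2. build the confound-matched primary dataset (A analogue) and, from
   subjects not used there, the generalization test sets: a second-disease
   set (A.1) and a 10-year age-gap set (A.2);
3. optionally build the age-classification arm (B) by matching older
   controls to 10-year-younger controls, with its own generalization sets
   (B.1: disease, B.2: second disease);
4. split matched pairs in tandem (64/16/20), assemble per-bundle feature
   tensors with split-local imputation and train-fitted z-scoring;
5. train one CNN per bundle (plus one logistic baseline per bundle on the
   primary dataset) and evaluate on held-out test pairs: DeLong AUC
   variance, Bonferroni chance bands across the three bundles, FDR-
   corrected pairwise bundle comparisons, and frozen-model cross-task
   applications.

Every artifact (config, matched sets, scores, metrics, histories) is
written to a run directory; reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, evaluation, features, matching, models
from .cohort import BUNDLES, CohortConfig, EffectConfig


@dataclass
class ExperimentConfig:
    """Everything a full experiment run depends on."""
    seed: int = 0
    n_case: int = 905
    n_control: int = 5292
    n_amd: int = 81
    amd_age_mean: float = 70.0
    max_logmar: float = 0.3
    confounders: tuple = matching.DEFAULT_CONFOUNDERS
    threshold: float = matching.DEFAULT_THRESHOLD
    age_shift: float = 10.0
    split_fractions: tuple = (0.64, 0.16, 0.20)
    bundles: tuple = BUNDLES
    aging: bool = True               # give profiles a global age drift
    effect_scale: float = 1.0        # multiplies all group-offset curves
    include_age_arm: bool = True     # train the age-classification CNNs (B)
    alpha: float = 0.05
    lr: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 30
    patience: int = 5
    save_profiles: bool = False

    def train_config(self, seed: int) -> models.TrainConfig:
        return models.TrainConfig(lr=self.lr, batch_size=self.batch_size,
                                  max_epochs=self.max_epochs,
                                  patience=self.patience, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("confounders", "split_fractions", "bundles"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        for b in self.bundles:
            if b not in BUNDLES:
                raise ValueError(f"unknown bundle {b!r}")


def _seed_table(seed: int, n: int = 64) -> np.ndarray:
    return (np.random.SeedSequence(seed).generate_state(n)
            & np.uint32(0x7FFFFFFF)).astype(np.int64)


def _stage(name):
    """Label failures with the pipeline stage they came from."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def _pair_roster(pairs: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Subjects of a matched set, relabeled by pairing role (pos/neg)."""
    sub = subjects.set_index("id")
    rows = []
    for role, col in (("pos", "case_id"), ("neg", "control_id")):
        part = sub.loc[pairs[col]].reset_index().rename(columns={"index": "id"})
        part["label"] = role
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def _assert_disjoint(train_ids, test_ids, what: str) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise AssertionError(
            f"{what}: {len(overlap)} subject(s) appear in both train and test")


def _mean_age_gap(pairs: pd.DataFrame, subjects: pd.DataFrame) -> float:
    age = subjects.set_index("id")["age"]
    return float(age.loc[pairs["case_id"]].mean()
                 - age.loc[pairs["control_id"]].mean())


def _evaluate_family(scores_by_bundle: dict, y_by_bundle: dict,
                     alpha: float) -> dict:
    """Per-bundle EvalResults with Bonferroni chance bands over the family."""
    out = {}
    n_tests = len(scores_by_bundle)
    for bundle, scores in scores_by_bundle.items():
        res = evaluation.roc_auc(scores, y_by_bundle[bundle])
        res.ci, res.significant = evaluation.chance_band(
            res.auc, res.variance, alpha=alpha, n_tests=n_tests)
        out[bundle] = res
    return out


def run_experiment(config: ExperimentConfig, run_dir) -> dict:
    """Execute the full experiment; return (and write) the metrics report."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seeds = _seed_table(config.seed)
    config.to_yaml(run_dir / "config.yaml")
    report: dict = {"seed": config.seed}

    with _stage("simulate"):
        glauc = cohort.generate_subjects(
            config.n_case, 0, int(seeds[0]), case_label="glaucoma",
            id_prefix="G")
        controls = cohort.generate_subjects(
            0, config.n_control, int(seeds[1]), id_prefix="C")
        amd = cohort.generate_subjects(
            config.n_amd, 0, int(seeds[2]),
            CohortConfig(case_age_mean=config.amd_age_mean),
            case_label="amd", id_prefix="M")
        glauc = cohort.apply_eligibility(glauc, config.max_logmar)
        controls = cohort.apply_eligibility(controls, config.max_logmar)
        amd = cohort.apply_eligibility(amd, config.max_logmar)
        subjects = pd.concat([glauc, controls, amd], ignore_index=True)

        base = EffectConfig()
        if config.aging:
            base = base.with_aging()
        s = config.effect_scale
        glauc_eff = _cfg_offsets(
            base, {k: s * v for k, v in base.offsets.items()})
        ctrl_eff = _cfg_offsets(base, {})
        amd_eff = _cfg_offsets(
            base, {k: s * v for k, v in cohort.amd_like_offsets().items()})
        profiles = pd.concat([
            cohort.generate_profiles(glauc, glauc_eff, int(seeds[3]),
                                     case_label="glaucoma"),
            cohort.generate_profiles(controls, ctrl_eff, int(seeds[4])),
            cohort.generate_profiles(amd, amd_eff, int(seeds[5]),
                                     case_label="amd"),
        ], ignore_index=True)
        profiles = cohort.inject_missingness(profiles, base, int(seeds[6]))
        cohort.write_subjects(subjects, run_dir / "subjects.csv")
        if config.save_profiles:
            cohort.write_profiles(profiles, run_dir / "profiles.csv")

    with _stage("match"):
        pairs_a = matching.match_cohorts(glauc, controls,
                                         confounders=config.confounders,
                                         threshold=config.threshold)
        pairs_a = matching.split_tandem(pairs_a, config.split_fractions,
                                        seed=int(seeds[7]))
        report["A"] = {
            "n_pairs": len(pairs_a),
            "pre_match_age_gap": float(glauc["age"].mean()
                                       - controls["age"].mean()),
            "post_match_age_gap": _mean_age_gap(pairs_a, subjects),
        }
        used_a = set(pairs_a["control_id"])
        pool_ca = pd.concat([controls, amd], ignore_index=True)
        pairs_a1 = matching.build_generalization_dataset(
            pool_ca, used_a, lambda df: df["label"].eq("amd"),
            threshold=config.threshold, confounders=config.confounders)
        pairs_a2 = matching.build_generalization_dataset(
            controls, used_a,
            lambda df: (df["age"] >= 69.5) & (df["age"] < 70.5),
            age_shift=config.age_shift, threshold=config.threshold,
            confounders=config.confounders)
        matching.write_matched(pairs_a, run_dir / "matched_A.csv")
        matching.write_matched(pairs_a1, run_dir / "matched_A1.csv")
        matching.write_matched(pairs_a2, run_dir / "matched_A2.csv")
        report["A.1"] = {"n_pairs": len(pairs_a1)}
        report["A.2"] = {"n_pairs": len(pairs_a2),
                         "age_gap": _mean_age_gap(pairs_a2, subjects)}

    # -- primary models on dataset A ---------------------------------------
    cnn_models, cnn_norms, cnn_scores, logit_scores = {}, {}, {}, {}
    y_test: dict = {}
    with _stage("train-A"):
        roster_a = _pair_roster(pairs_a, subjects)
        splits_a = matching.subject_splits(pairs_a)
        for k, bundle in enumerate(config.bundles):
            tensors = features.assemble_split_tensors(
                profiles, bundle, roster_a, splits_a, case_label="pos")
            _assert_disjoint(tensors["train"].ids, tensors["test"].ids,
                             f"dataset A / {bundle}")
            imputed = {s: features.impute_missing(t) for s, t in tensors.items()}
            norm, tr, (va, te) = features.zscore_fit_apply(
                imputed["train"], [imputed["validation"], imputed["test"]])
            model = models.build_cnn(seed=int(seeds[8 + k]))
            history = models.train_cnn(model, tr, va,
                                       config.train_config(int(seeds[16 + k])))
            history.to_csv(run_dir / f"history_A_cnn_{bundle}.csv", index=False)
            cnn_models[bundle], cnn_norms[bundle] = model, norm
            cnn_scores[bundle] = model.predict_proba(te.X)
            y_test[bundle] = te.y
            _write_scores(run_dir / f"scores_A_cnn_{bundle}.csv",
                          te.ids, cnn_scores[bundle], te.y)

            # logistic baseline on sparse node features
            fsplit = {}
            for split_name in ("train", "validation", "test"):
                roster_s = roster_a.merge(
                    splits_a[splits_a["split"] == split_name],
                    left_on="id", right_on="subject_id")
                F, _, ids, y = features.logistic_features(
                    profiles, bundle, roster_s, case_label="pos")
                fsplit[split_name] = (features.impute_feature_matrix(F), ids, y)
            logit = models.fit_logistic_ridge(
                fsplit["train"][0], fsplit["train"][2],
                fsplit["validation"][0], fsplit["validation"][2])
            Fte, ids_te, yte = fsplit["test"]
            logit_scores[bundle] = logit.predict_proba(Fte)
            _write_scores(run_dir / f"scores_A_logistic_{bundle}.csv",
                          ids_te, logit_scores[bundle], yte)

    with _stage("evaluate-A"):
        cnn_evals = _evaluate_family(cnn_scores, y_test, config.alpha)
        logit_evals = _evaluate_family(logit_scores, y_test, config.alpha)
        report["A"]["cnn"] = {b: r.to_dict() for b, r in cnn_evals.items()}
        report["A"]["logistic"] = {b: r.to_dict() for b, r in logit_evals.items()}
        comparisons = {}
        if "OR" in cnn_scores:
            pz = {}
            for other in [b for b in ("CST", "UNC") if b in cnn_scores]:
                z, p = evaluation.delong_test_paired(
                    cnn_scores["OR"], cnn_scores[other], y_test["OR"])
                pz[f"cnn_or_vs_{other.lower()}"] = (z, p)
            adj = evaluation.fdr_adjust([p for _, p in pz.values()])
            for (name, (z, p)), q in zip(pz.items(), adj):
                comparisons[name] = {"z": z, "p": p, "p_fdr": float(q)}
            z, p = evaluation.delong_test_paired(
                cnn_scores["OR"], logit_scores["OR"], y_test["OR"])
            comparisons["cnn_vs_logistic_or"] = {"z": z, "p": p}
            report["A"]["confusion"] = {
                "cnn_OR": evaluation.confusion(cnn_scores["OR"], y_test["OR"]),
                "logistic_OR": evaluation.confusion(logit_scores["OR"],
                                                    y_test["OR"]),
            }
        report["A"]["comparisons"] = comparisons

    with _stage("generalize-A"):
        for name, pairs_g in (("A.1", pairs_a1), ("A.2", pairs_a2)):
            report[name]["cnn"] = _cross_dataset(
                name, pairs_g, subjects, profiles, config,
                cnn_models, cnn_norms, pairs_a, run_dir)

    # -- age-classification arm (dataset B) --------------------------------
    if config.include_age_arm:
        with _stage("match-B"):
            pairs_b = matching.build_generalization_dataset(
                controls, set(),
                lambda df: (df["age"] >= 70.0) & (df["age"] < 80.0),
                age_shift=config.age_shift, threshold=config.threshold,
                confounders=config.confounders)
            pairs_b = matching.split_tandem(pairs_b, config.split_fractions,
                                            seed=int(seeds[24]))
            matching.write_matched(pairs_b, run_dir / "matched_B.csv")
            used_b = set(pairs_b["case_id"]) | set(pairs_b["control_id"])
            pool_cg = pd.concat([controls, glauc], ignore_index=True)
            pairs_b1 = matching.build_generalization_dataset(
                pool_cg, used_b,
                lambda df: df["label"].eq("glaucoma") & (df["age"] >= 60.0)
                & (df["age"] < 65.0),
                threshold=config.threshold, confounders=config.confounders)
            pairs_b2 = matching.build_generalization_dataset(
                pool_ca, used_b, lambda df: df["label"].eq("amd"),
                threshold=config.threshold, confounders=config.confounders)
            report["B"] = {"n_pairs": len(pairs_b),
                           "age_gap": _mean_age_gap(pairs_b, subjects)}
            report["B.1"] = {"n_pairs": len(pairs_b1)}
            report["B.2"] = {"n_pairs": len(pairs_b2)}

        bcnn_models, bcnn_norms, bcnn_scores, by_test = {}, {}, {}, {}
        with _stage("train-B"):
            roster_b = _pair_roster(pairs_b, subjects)
            splits_b = matching.subject_splits(pairs_b)
            for k, bundle in enumerate(config.bundles):
                tensors = features.assemble_split_tensors(
                    profiles, bundle, roster_b, splits_b, case_label="pos")
                _assert_disjoint(tensors["train"].ids, tensors["test"].ids,
                                 f"dataset B / {bundle}")
                imputed = {s: features.impute_missing(t)
                           for s, t in tensors.items()}
                norm, tr, (va, te) = features.zscore_fit_apply(
                    imputed["train"],
                    [imputed["validation"], imputed["test"]])
                model = models.build_cnn(seed=int(seeds[32 + k]))
                history = models.train_cnn(
                    model, tr, va, config.train_config(int(seeds[40 + k])))
                history.to_csv(run_dir / f"history_B_cnn_{bundle}.csv",
                               index=False)
                bcnn_models[bundle], bcnn_norms[bundle] = model, norm
                bcnn_scores[bundle] = model.predict_proba(te.X)
                by_test[bundle] = te.y
                _write_scores(run_dir / f"scores_B_cnn_{bundle}.csv",
                              te.ids, bcnn_scores[bundle], te.y)

        with _stage("evaluate-B"):
            b_evals = _evaluate_family(bcnn_scores, by_test, config.alpha)
            report["B"]["cnn"] = {b: r.to_dict() for b, r in b_evals.items()}
            pairwise = {}
            bl = list(config.bundles)
            pvals = []
            names = []
            for i in range(len(bl)):
                for j in range(i + 1, len(bl)):
                    z, p = evaluation.delong_test_paired(
                        bcnn_scores[bl[i]], bcnn_scores[bl[j]], by_test[bl[i]])
                    names.append(f"cnn_{bl[i].lower()}_vs_{bl[j].lower()}")
                    pvals.append((z, p))
            adj = evaluation.fdr_adjust([p for _, p in pvals])
            for name, (z, p), q in zip(names, pvals, adj):
                pairwise[name] = {"z": z, "p": p, "p_fdr": float(q)}
            report["B"]["comparisons"] = pairwise

        with _stage("generalize-B"):
            for name, pairs_g in (("B.1", pairs_b1), ("B.2", pairs_b2)):
                report[name]["cnn"] = _cross_dataset(
                    name, pairs_g, subjects, profiles, config,
                    bcnn_models, bcnn_norms, pairs_b, run_dir)

    with open(run_dir / "metrics.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
    return report


def _cfg_offsets(cfg: EffectConfig, offsets: dict) -> EffectConfig:
    return replace(cfg, offsets=offsets)


def _write_scores(path, ids, scores, labels) -> None:
    pd.DataFrame({"subject_id": ids, "score": scores,
                  "label": labels}).to_csv(path, index=False)


def _cross_dataset(name, pairs_g, subjects, profiles, config,
                   model_by_bundle, norm_by_bundle, train_pairs,
                   run_dir) -> dict:
    """Apply frozen per-bundle models to a generalization dataset."""
    if len(pairs_g) == 0:
        warnings.warn(f"{name}: empty matched set; skipping", stacklevel=2)
        return {}
    roster = _pair_roster(pairs_g, subjects)
    train_ids = matching.subject_splits(train_pairs)
    train_ids = set(train_ids.loc[train_ids["split"] == "train", "subject_id"])
    _assert_disjoint(train_ids, roster["id"], f"dataset {name}")
    out = {}
    n_tests = len(config.bundles)
    for bundle in config.bundles:
        tensor = features.assemble_tensor(profiles, bundle, roster,
                                          case_label="pos")
        tensor = features.impute_missing(tensor)
        res = evaluation.cross_apply(model_by_bundle[bundle], tensor,
                                     normalizer=norm_by_bundle[bundle],
                                     alpha=config.alpha, n_tests=n_tests)
        _write_scores(run_dir / f"scores_{name.replace('.', '')}_cnn_{bundle}.csv",
                      tensor.ids,
                      model_by_bundle[bundle].predict_proba(
                          norm_by_bundle[bundle].apply(tensor).X),
                      tensor.y)
        out[bundle] = res.to_dict()
    return out


# ---------------------------------------------------------------------------
# reporting


def _fmt_eval(d: dict) -> str:
    ci = d.get("ci")
    ci_s = f"[{ci[0]:.3f}, {ci[1]:.3f}]" if ci else "—"
    sig = {True: "yes", False: "no", None: "—"}[d.get("significant")]
    return (f"{d['auc']:.3f} | {ci_s} | {sig} "
            f"| {d['n_pos'] + d['n_neg']}")


def make_report(run_dir) -> str:
    """Human-readable summary of one run (or several same-config runs).

    Tabulates AUCs with Bonferroni-corrected CIs and significance flags,
    comparison p-values, and — when ``run_dir`` holds several runs with
    different seeds — the across-seed AUC spread.  Renders ROC curves from
    the stored score files.  Returns the summary text (also written to
    ``report.md``).
    """
    run_dir = Path(run_dir)
    metric_files = ([run_dir / "metrics.json"]
                    if (run_dir / "metrics.json").exists()
                    else sorted(run_dir.glob("*/metrics.json")))
    reports = []
    for mf in metric_files:
        with open(mf) as fh:
            reports.append(json.load(fh))
    lines = ["# Experiment report", ""]
    if not reports:
        lines.append("No metrics found in this run directory.")
        text = "\n".join(lines)
        (run_dir / "report.md").write_text(text)
        return text

    rep = reports[0]
    for ds in ("A", "A.1", "A.2", "B", "B.1", "B.2"):
        if ds not in rep:
            lines.append(f"## Dataset {ds}: absent from this run")
            lines.append("")
            continue
        block = rep[ds]
        lines.append(f"## Dataset {ds} (n_pairs = {block.get('n_pairs', '—')})")
        for key in ("pre_match_age_gap", "post_match_age_gap", "age_gap"):
            if key in block:
                lines.append(f"- {key.replace('_', ' ')}: {block[key]:.2f} years")
        for family in ("cnn", "logistic"):
            if family in block and block[family]:
                lines.append("")
                lines.append(f"| {family.upper()} bundle | AUC | CI | sig vs 0.5 | n |")
                lines.append("|---|---|---|---|---|")
                for bundle, d in block[family].items():
                    lines.append(f"| {bundle} | {_fmt_eval(d)} |")
        if block.get("comparisons"):
            lines.append("")
            lines.append("| comparison | z | p | p (FDR) |")
            lines.append("|---|---|---|---|")
            for name, d in block["comparisons"].items():
                q = f"{d['p_fdr']:.4f}" if "p_fdr" in d else "—"
                lines.append(f"| {name} | {d['z']:.3f} | {d['p']:.4f} | {q} |")
        lines.append("")

    if len(reports) > 1:
        lines.append("## Across-seed AUC spread (dataset A CNNs)")
        lines.append("")
        lines.append("| bundle | mean | min | max | runs |")
        lines.append("|---|---|---|---|---|")
        by_bundle: dict[str, list] = {}
        for r in reports:
            for bundle, d in r.get("A", {}).get("cnn", {}).items():
                by_bundle.setdefault(bundle, []).append(d["auc"])
        for bundle, aucs in by_bundle.items():
            lines.append(f"| {bundle} | {np.mean(aucs):.3f} | {min(aucs):.3f} "
                         f"| {max(aucs):.3f} | {len(aucs)} |")
        lines.append("")

    _plot_rocs(run_dir)
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text


def _plot_rocs(run_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    score_files = sorted(run_dir.glob("scores_*.csv"))
    if not score_files:
        return
    groups: dict[str, list[Path]] = {}
    for f in score_files:
        parts = f.stem.split("_")  # scores, dataset, model, bundle
        groups.setdefault("_".join(parts[1:3]), []).append(f)
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    for group, files in groups.items():
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        for f in files:
            df = pd.read_csv(f)
            res = evaluation.roc_auc(df["score"], df["label"],
                                     with_variance=False)
            bundle = f.stem.split("_")[-1]
            ax.plot(res.fpr, res.tpr, label=f"{bundle} (AUC {res.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(group)
        ax.legend()
        fig.tight_layout()
        fig.savefig(fig_dir / f"roc_{group}.png", dpi=120)
        plt.close(fig)
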