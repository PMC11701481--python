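"""JSON persistence of trained progression models.

Models are stored as human-inspectable JSON: matrices row-major as nested
lists with the feature-name order explicit, the covariate-adjustment and
standardization models, every selected member's prototypes and metric square
root, the averaged quantities, the configuration echo and the seed.  The
format round-trips bit-stably (floats serialized via ``repr``-faithful
``json`` with full precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CovariateAdjuster, FeatureStandardizer
from .ensemble import BalancedGmlvqEnsemble, EnsembleMember, ResamplePlan
from .gmlvq import GmlvqClassifier, relevance_matrix
from .pipeline import ProgressionModel
from .prognosis import PROTOTYPE_ANCHOR, BoundaryCalibration


def _arr(a: np.ndarray) -> list:
    return np.asarray(a, float).tolist()


def model_to_dict(model: ProgressionModel) -> dict:
    ens = model.ensemble_
    # a reloaded model only holds the selected members; map back to the
    # original member indices/accuracies so save -> load -> save is stable
    original_index = getattr(ens, "_member_original_indices_", None)
    all_accuracies = getattr(
        ens, "_all_member_accuracies_", [m.train_balanced_accuracy for m in ens.members_]
    )
    members = []
    for pos, i in enumerate(np.nonzero(ens.selected_)[0]):
        m: EnsembleMember = ens.members_[int(i)]
        members.append(
            {
                "index": int(original_index[pos]) if original_index is not None else int(i),
                "seed": int(m.seed),
                "train_balanced_accuracy": m.train_balanced_accuracy,
                "prototypes": _arr(m.model.prototypes_),
                "omega": _arr(m.model.omega_),
                "final_cost": float(m.model.cost_trace_[-1]),
                "classes": [str(c) for c in m.model.classes_],
            }
        )
    cal = model.calibration_
    return {
        "format": "mciprog-model",
        "version": __version__,
        "config": model.get_params(),
        "feature_names": model.feature_names_,
        "covariate_model": {
            "intercept": _arr(model.adjuster_.intercept_),
            "coef": _arr(model.adjuster_.coef_),
            "covariate_means": _arr(model.adjuster_.covariate_means_),
            "covariate_names": model.adjuster_.covariate_names_,
            "fit_subset": model.adjuster_.fit_subset_,
        },
        "standardizer": {
            "mean": _arr(model.standardizer_.mean_),
            "scale": _arr(model.standardizer_.scale_),
        },
        "ensemble": {
            "n_resamples": int(ens.plan_.n_resamples),
            "selection_fraction": float(ens.selection_fraction_),
            "classes": [str(c) for c in ens.classes_],
            "member_accuracies": list(all_accuracies),
            "selected_members": members,
            "averaged_prototypes": _arr(ens.averaged_prototypes_),
            "averaged_lambda": _arr(ens.averaged_lambda_),
        },
        "calibration": {
            "b_low": cal.b_low,
            "b_high": cal.b_high,
            "method": cal.method,
            "fitted_on": cal.fitted_on,
        },
    }


def model_from_dict(doc: dict) -> ProgressionModel:
    if doc.get("format") != "mciprog-model":
        raise ValueError("not a mciprog model document")
    model = ProgressionModel(**doc["config"])
    model.feature_names_ = list(doc["feature_names"])

    cm = doc["covariate_model"]
    adj = CovariateAdjuster()
    adj.intercept_ = np.asarray(cm["intercept"], float)
    adj.coef_ = np.asarray(cm["coef"], float)
    adj.covariate_means_ = np.asarray(cm["covariate_means"], float)
    adj.covariate_names_ = list(cm["covariate_names"])
    adj.feature_names_ = model.feature_names_
    adj.fit_subset_ = list(cm["fit_subset"])
    model.adjuster_ = adj

    st = doc["standardizer"]
    std = FeatureStandardizer()
    std.mean_ = np.asarray(st["mean"], float)
    std.scale_ = np.asarray(st["scale"], float)
    std.feature_names_ = model.feature_names_
    model.standardizer_ = std

    ed = doc["ensemble"]
    ens = BalancedGmlvqEnsemble(
        n_resamples=ed["n_resamples"],
        selection_fraction=ed["selection_fraction"],
    )
    ens.classes_ = np.asarray(ed["classes"], dtype=object)
    ens.n_features_in_ = len(model.feature_names_)
    # reconstruct the selected members as ready classifiers; unselected
    # members are not persisted (only their accuracies are)
    members: list[EnsembleMember] = []
    selected_flags = []
    for sm in ed["selected_members"]:
        clf = GmlvqClassifier()
        clf.classes_ = np.asarray(sm["classes"], dtype=object)
        clf._class_codes_ = np.sort(clf.classes_.astype(str))
        clf._order_lookup_ = np.array(
            [int(np.nonzero(clf.classes_.astype(str) == c)[0][0]) for c in clf._class_codes_]
        )
        clf.prototypes_ = np.asarray(sm["prototypes"], float)
        clf.omega_ = np.asarray(sm["omega"], float)
        clf.lambda_ = relevance_matrix(clf.omega_)
        clf.cost_trace_ = np.asarray([sm["final_cost"]])
        clf.n_features_in_ = len(model.feature_names_)
        members.append(
            EnsembleMember(clf, float(sm["train_balanced_accuracy"]), int(sm["seed"]))
        )
        selected_flags.append(True)
    ens.members_ = members
    ens._member_original_indices_ = [int(sm["index"]) for sm in ed["selected_members"]]
    ens._all_member_accuracies_ = [float(v) for v in ed["member_accuracies"]]
    ens.selected_ = np.asarray(selected_flags, dtype=bool)
    ens.selection_fraction_ = float(ed["selection_fraction"])
    ens.averaged_prototypes_ = np.asarray(ed["averaged_prototypes"], float)
    ens.averaged_lambda_ = np.asarray(ed["averaged_lambda"], float)
    ens.plan_ = ResamplePlan(ed["n_resamples"], (), ())
    model.ensemble_ = ens

    cd = doc["calibration"]
    model.calibration_ = (
        PROTOTYPE_ANCHOR
        if cd["method"] == "prototype_anchor" and cd["b_low"] == 0.0 and cd["b_high"] == 1.0
        else BoundaryCalibration(cd["b_low"], cd["b_high"], cd["method"], cd["fitted_on"])
    )
    return model


def save_model(model: ProgressionModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> ProgressionModel:
    return model_from_dict(json.loads(Path(path).read_text()))
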