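"""End-to-end study driver: phantom cohort to ROC comparison.

Chains the full procedure on an in-memory cohort: histogram
equalization, landmark signature normalization, ROI cropping, phase
congruency and Gabor response maps, the eight texture measures, KS
normality screening on the control split, LDF/QDF discrimination with
error rates at C = 1, and the ROC/AUC sweep on the held-out test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gabor as gabor_mod
from . import normalize as norm_mod
from . import roc as roc_mod
from . import stats as stats_mod
from . import texture as tex_mod
from .pc import PCParams, phase_congruency_map
from .radiograph import Radiograph

PAIRS = (("LC", "NL"), ("PNEU", "NL"), ("LC", "PNEU"))


@dataclass
class StudyResult:
    """Tables produced by one end-to-end run."""

    features: pd.DataFrame  # id, class, source, split, eight measures
    signature: norm_mod.CentralSignature
    normality: pd.DataFrame  # source, measure, class, K-stat, critical, accept
    errors: pd.DataFrame  # source, pair, measure, delta, beta (C = 1)
    aucs: pd.DataFrame  # source, pair, measure, auc
    extras: dict = field(default_factory=dict)


def extract_features(
    cohort: list[Radiograph],
    *,
    pc_params: PCParams | None = None,
    gabor_params: gabor_mod.GaborBankParams | None = None,
    levels: int = 256,
    offset: tuple[int, int] = (0, 1),
    landmark_radius: int = 3,
) -> tuple[pd.DataFrame, norm_mod.CentralSignature]:
    """Normalize a cohort and compute PC and Gabor texture features."""
    if pc_params is None:
        pc_params = PCParams()
    if gabor_params is None:
        gabor_params = gabor_mod.GaborBankParams(
            lambda_min=pc_params.lambda_min, alpha=pc_params.alpha
        )

    equalized = [norm_mod.equalize_histogram(r.pixels, r.bit_depth) for r in cohort]
    landmark_sets = [
        norm_mod.extract_landmark_intensities(img, rad.landmarks, landmark_radius)
        for img, rad in zip(equalized, cohort)
    ]
    signature = norm_mod.compute_central_signature(landmark_sets)

    rows = []
    for i, (rad, img, s) in enumerate(zip(cohort, equalized, signature.signatures)):
        normalized = norm_mod.normalize_image(img, float(s))
        roi = norm_mod.crop_roi(normalized, rad.roi_box)

        pc_map = phase_congruency_map(roi, pc_params)
        tv_pc = tex_mod.texture_vector(
            pc_map.pc, levels=levels, offset=offset, channel_stack=pc_map.amplitudes
        )
        rows.append({"id": i, "class": rad.label, "source": "pc", **tv_pc.as_dict()})

        gab = gabor_mod.gabor_bank_response(roi, gabor_params)
        tv_g = tex_mod.texture_vector(
            gab.combined, levels=levels, offset=offset, channel_stack=gab.responses
        )
        rows.append({"id": i, "class": rad.label, "source": "gabor", **tv_g.as_dict()})
    return pd.DataFrame(rows), signature


def split_control_test(features: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Add a per-image 'split' column: half control, half test per class."""
    rng = np.random.default_rng(seed)
    features = features.copy()
    features["split"] = "test"
    ids = features[["id", "class"]].drop_duplicates()
    for label, group in ids.groupby("class"):
        perm = rng.permutation(group["id"].to_numpy())
        control = set(perm[: len(perm) // 2])
        features.loc[
            features["id"].isin(control) & (features["class"] == label), "split"
        ] = "control"
    return features


def run_study(
    n_nl: int = 40,
    n_lc: int = 50,
    n_pneu: int = 50,
    seed: int = 0,
    *,
    image_size: int = 512,
    noise_sd: float = 15.0,
    measures: tuple[str, ...] = tex_mod.MEASURES,
    levels: int = 256,
    pc_params: PCParams | None = None,
    ks_convention: str = "c94",
) -> StudyResult:
    """Run the full discrimination study on a phantom cohort."""
    from .synth import generate_cohort

    cohort = generate_cohort(
        n_nl, n_lc, n_pneu, seed, width=image_size, height=image_size, noise_sd=noise_sd
    )
    features, signature = extract_features(cohort, pc_params=pc_params, levels=levels)
    features = split_control_test(features, seed)

    normality_rows = []
    error_rows = []
    auc_rows = []
    for source in ("pc", "gabor"):
        sub = features[features["source"] == source]
        control = sub[sub["split"] == "control"]
        test = sub[sub["split"] == "test"]
        for measure in measures:
            for label in ("NL", "LC", "PNEU"):
                vals = control.loc[control["class"] == label, measure].to_numpy()
                if vals.size >= 5 and np.isfinite(vals).all() and vals.std(ddof=1) > 0:
                    res = stats_mod.ks_normality(vals, convention=ks_convention)
                    normality_rows.append(
                        {
                            "source": source,
                            "measure": measure,
                            "class": label,
                            "k_stat": res.k_stat,
                            "critical_value": res.critical_value,
                            "accept": res.accept,
                        }
                    )
            for pos, neg in PAIRS:
                c1 = control.loc[control["class"] == pos, measure].to_numpy()
                c2 = control.loc[control["class"] == neg, measure].to_numpy()
                t1 = test.loc[test["class"] == pos, measure].to_numpy()
                t2 = test.loc[test["class"] == neg, measure].to_numpy()
                if min(c1.size, c2.size, t1.size, t2.size) < 2:
                    continue
                if c1.var(ddof=1) == 0 or c2.var(ddof=1) == 0:
                    continue
                model = stats_mod.fit_discriminant(c1, c2)
                err = stats_mod.error_rates(model, t1, t2, cost_ratio=1.0)
                error_rows.append(
                    {
                        "source": source,
                        "pair": f"{pos}-{neg}",
                        "measure": measure,
                        "form": model.form,
                        "delta": err.delta,
                        "beta": err.beta,
                    }
                )
                curve = roc_mod.roc_curve(model, t1, t2)
                auc_rows.append(
                    {
                        "source": source,
                        "pair": f"{pos}-{neg}",
                        "measure": measure,
                        "auc": curve.auc,
                    }
                )

    return StudyResult(
        features=features,
        signature=signature,
        normality=pd.DataFrame(normality_rows),
        errors=pd.DataFrame(error_rows),
        aucs=pd.DataFrame(auc_rows),
    )
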