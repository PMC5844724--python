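"""File formats, configuration and the end-to-end study runner.

Canonical on-disk formats: NIfTI (``.nii``/``.nii.gz``) for images and
masks, CSV for tables, JSON for configuration. Masks are binarized at
``> 0``. Every emitted table is stamped with a hash of the configuration
and the master seed (a ``#`` comment line) so results are traceable to the
exact settings that produced them.

:func:`run_study` chains the full analysis: simulate (or ingest) the
cohort, extract features per (patient, timepoint, rater), tabulate
interobserver ICC per parameter and timepoint, average raters, run the
group comparisons under both reference standards (TRG responder and pCR),
then the per-feature ROC analyses, the backward-elimination logistic
combination and the paired DeLong comparisons of combined vs single
predictors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import agreement, groupstats, phantom, plots, response
from .features import FEATURE_NAMES, MaskedImage, extract_features

__all__ = [
    "StudyConfig",
    "read_image_mask",
    "write_image_mask",
    "write_feature_table",
    "read_feature_table",
    "extract_cohort",
    "icc_table",
    "run_study",
    "write_cohort_to_disk",
    "load_cohort_from_disk",
]

logger = logging.getLogger("larctex")

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class StudyConfig:
    """Settings of one end-to-end study run."""

    seed: int = 0
    n_bins: int = 32
    alpha: float = 0.05
    icc_model: str = "ICC(2,1)"
    labels: tuple[str, ...] = ("trg", "pcr")
    cutoff_criterion: str = "youden"
    selection_criterion: str = "wald"
    uniformity_mode: str = "standard"
    energy_mode: str = "minmax"
    holm: bool = False
    # cohort structure (simulate mode)
    n_responders_trg: int = 30
    n_nonresponders_trg: int = 29
    n_pcr: int = 15
    rater_jitter: float = 1.0
    # file mode: directory holding images/, masks/ and labels.csv
    data_dir: str | None = None
    out_dir: str | None = None

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def cohort_spec(self) -> phantom.CohortSpec:
        return phantom.CohortSpec(
            n_responders_trg=self.n_responders_trg,
            n_nonresponders_trg=self.n_nonresponders_trg,
            n_pcr=self.n_pcr,
            seed=self.seed,
            rater_jitter=self.rater_jitter,
        )

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "labels" in data:
            data["labels"] = tuple(data["labels"])
        return cls(**data)


def read_image_mask(
    image_path,
    mask_path,
    patient_id: str = "",
    timepoint: str = "pre",
    rater: str = "",
    slice_index: int | str | None = None,
) -> MaskedImage:
    """Load an image/mask NIfTI pair as a validated :class:`MaskedImage`.

    3D volumes require ``slice_index`` — an integer plane (last axis) or
    ``"largest"`` to pick the slice with the maximal mask area, the
    single-slice convention for tumor delineation. Masks are binarized at
    ``> 0``; a shape mismatch or empty mask is an error.
    """
    img = np.asanyarray(nib.load(str(image_path)).dataobj).squeeze()
    msk = np.asanyarray(nib.load(str(mask_path)).dataobj).squeeze()
    if img.shape != msk.shape:
        raise ValueError(f"image shape {img.shape} does not match mask shape {msk.shape}")
    mask = msk > 0
    if img.ndim == 3:
        if slice_index is None:
            raise ValueError("3D volume: pass slice_index (an int or 'largest')")
        if slice_index == "largest":
            areas = mask.sum(axis=(0, 1))
            slice_index = int(np.argmax(areas))
        img = img[:, :, int(slice_index)]
        mask = mask[:, :, int(slice_index)]
    elif img.ndim != 2:
        raise ValueError(f"expected a 2D slice or 3D volume, got shape {img.shape}")
    if not mask.any():
        raise ValueError(f"empty mask in {mask_path}")
    return MaskedImage(
        pixels=np.asarray(img, dtype=float),
        mask=mask,
        patient_id=patient_id,
        timepoint=timepoint,
        rater=rater,
    )


def write_image_mask(img: MaskedImage, image_path, mask_path) -> None:
    """Write an image/mask pair as NIfTI files."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(img.pixels.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(img.mask.astype(np.uint8), affine), str(mask_path))


def _stamp(path: Path, config: StudyConfig | None) -> None:
    if config is None:
        return
    text = path.read_text()
    path.write_text(
        f"# config_hash={config.config_hash()} seed={config.seed}\n{text}"
    )


def write_feature_table(cohort: pd.DataFrame, path, config: StudyConfig | None = None) -> None:
    """Write a cohort table to CSV (12 significant digits, lossless round
    trip), optionally stamped with the config hash/seed comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _stamp(path, config)


def read_feature_table(path) -> pd.DataFrame:
    """Read a cohort table back; duplicate (patient, timepoint, rater)
    rows are rejected."""
    df = pd.read_csv(path, comment="#")
    if set(groupstats.KEY_COLUMNS) <= set(df.columns):
        dup = df.duplicated(subset=list(groupstats.KEY_COLUMNS))
        if dup.any():
            key = df.loc[dup.idxmax(), list(groupstats.KEY_COLUMNS)].tolist()
            raise ValueError(f"duplicate (patient, timepoint, rater) row: {key}")
    return df


def extract_cohort(
    images: list[MaskedImage],
    labels: pd.DataFrame,
    config: StudyConfig = StudyConfig(),
) -> pd.DataFrame:
    """Extract features for every image and join the response labels."""
    rows = []
    for img in images:
        feats = extract_features(
            img,
            config.n_bins,
            uniformity_mode=config.uniformity_mode,
            energy_mode=config.energy_mode,
        )
        row = {
            "patient_id": img.patient_id,
            "timepoint": img.timepoint,
            "rater": img.rater,
            **feats.as_dict(),
            "n_bins_used": feats.n_bins_used,
            "n_pixels": feats.n_pixels,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    keep = [c for c in ("patient_id", "trg", "responder_trg", "pcr") if c in labels.columns]
    table = table.merge(labels[keep], on="patient_id", how="left", validate="many_to_one")
    return groupstats.validate_cohort(table)


def icc_table(cohort: pd.DataFrame, raters: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Interobserver ICC of each parameter at each timepoint."""
    rows = []
    for timepoint in ("pre", "early"):
        sub = cohort[cohort["timepoint"] == timepoint]
        a = sub[sub["rater"] == raters[0]].set_index("patient_id")
        b = sub[sub["rater"] == raters[1]].set_index("patient_id")
        common = a.index.intersection(b.index)
        for name in FEATURE_NAMES:
            res = agreement.icc_agreement(
                a.loc[common, name].to_numpy(), b.loc[common, name].to_numpy()
            )
            rows.append(
                {
                    "timepoint": timepoint,
                    "parameter": name,
                    "icc": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "model": res.model,
                    "band": res.band,
                    "n_subjects": res.n_subjects,
                }
            )
    return pd.DataFrame(rows)


def _roc_row(name: str, r: response.ROCResult) -> dict:
    return {
        "parameter": name,
        "cutoff": r.cutoff,
        "direction": r.direction,
        "auc": r.auc,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "sensitivity_pct": r.sensitivity,
        "specificity_pct": r.specificity,
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
        "performance": "apparent",
    }


def response_analysis(
    cohort_avg: pd.DataFrame,
    label: str,
    config: StudyConfig = StudyConfig(),
) -> dict:
    """ROC + logistic-combination analysis for one reference standard.

    Candidate features are the pre-treatment parameters univariately
    significant at ``config.alpha`` (Mann-Whitney gate). Each gets a
    univariate ROC row; if >= 2 pass the gate, a backward-elimination
    logistic model combines them and the combined predictor's ROC and
    paired DeLong comparisons against each retained single feature are
    added.
    """
    label_col = "pcr" if label == "pcr" else "responder_trg"
    pre = cohort_avg[cohort_avg["timepoint"] == "pre"].reset_index(drop=True)
    y = pre[label_col].to_numpy(dtype=bool)
    tables = groupstats.run_group_tables(cohort_avg, label=label, alpha=config.alpha,
                                         holm=config.holm)
    sig = tables["response"]
    candidates = [
        r["feature"]
        for _, r in sig[(sig["timepoint"] == "pre") & (sig["p"] < config.alpha)].iterrows()
    ]
    roc_rows = []
    curves = {}
    oriented = {}
    for name in candidates:
        r = response.roc_analysis(pre[name], y)
        roc_rows.append(_roc_row(f"pre-{name}", r))
        curves[f"pre-{name}"] = response.roc_curve_points(pre[name], y)
        # orient so higher score = positive class, as tabulated AUCs are
        sign = 1.0 if r.direction == ">" else -1.0
        oriented[name] = sign * pre[name].to_numpy(dtype=float)

    model = None
    delong_rows = []
    if len(candidates) >= 2:
        model = response.select_features_backward(
            pre[candidates], y, alpha=config.alpha, criterion=config.selection_criterion
        )
        if not model.intercept_only:
            probs = model.probabilities
            r = response.roc_analysis(probs, y)
            roc_rows.append(_roc_row("logistic_combined", r))
            curves["logistic_combined"] = response.roc_curve_points(probs, y)
            for name in candidates:
                auc_c, auc_s, diff, p = response.compare_auc_delong(probs, oriented[name], y)
                delong_rows.append(
                    {
                        "comparison": f"combined_vs_pre-{name}",
                        "auc_combined": auc_c,
                        "auc_single": auc_s,
                        "difference": diff,
                        "p": p,
                    }
                )
    return {
        "group_tables": tables,
        "candidates": candidates,
        "roc": pd.DataFrame(roc_rows),
        "curves": curves,
        "model": model,
        "delong": pd.DataFrame(delong_rows),
    }


def write_cohort_to_disk(images: list[MaskedImage], labels: pd.DataFrame, out_dir) -> Path:
    """Write a simulated cohort as NIfTI pairs plus a labels/manifest CSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        stem = f"{img.patient_id}_{img.timepoint}_{img.rater}"
        ipath = out / "images" / f"{stem}.nii.gz"
        mpath = out / "masks" / f"{stem}_mask.nii.gz"
        write_image_mask(img, ipath, mpath)
        rows.append(
            {
                "patient_id": img.patient_id,
                "timepoint": img.timepoint,
                "rater": img.rater,
                "image": str(ipath.relative_to(out)),
                "mask": str(mpath.relative_to(out)),
            }
        )
    manifest = pd.DataFrame(rows).merge(labels, on="patient_id", how="left")
    manifest.to_csv(out / "labels.csv", index=False, float_format=_FLOAT_FMT)
    return out / "labels.csv"


def load_cohort_from_disk(data_dir) -> tuple[list[MaskedImage], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort_to_disk`."""
    root = Path(data_dir)
    manifest = pd.read_csv(root / "labels.csv")
    images = [
        read_image_mask(
            root / r["image"],
            root / r["mask"],
            patient_id=r["patient_id"],
            timepoint=r["timepoint"],
            rater=r["rater"],
        )
        for _, r in manifest.iterrows()
    ]
    labels = manifest.drop_duplicates("patient_id")[
        [c for c in ("patient_id", "trg", "responder_trg", "pcr") if c in manifest.columns]
    ].reset_index(drop=True)
    return images, labels


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline and (optionally) write the report bundle.

    Returns a dict with the cohort table, the ICC table, and per-label
    group/ROC/logistic results. With ``config.out_dir`` set, every table is
    written as a stamped CSV and ROC coordinates are saved per predictor.
    """
    t0 = time.time()
    if config.data_dir:
        images, labels = load_cohort_from_disk(config.data_dir)
        stage = "ingest"
    else:
        images, labels = phantom.generate_cohort(config.cohort_spec())
        stage = "simulate"
    logger.info("%s: %d images, %d patients (%.2fs)", stage, len(images), len(labels),
                time.time() - t0)

    cohort = extract_cohort(images, labels, config)
    logger.info("extract: %d feature rows", len(cohort))

    icc = icc_table(cohort)
    logger.info("agree: %d ICC rows, range %.2f-%.2f", len(icc),
                icc["icc"].min(), icc["icc"].max())

    averaged = groupstats.average_raters(cohort)
    logger.info("average_raters: %d rows", len(averaged))

    results = {"cohort": cohort, "cohort_averaged": averaged, "icc": icc, "config": config}
    for label in config.labels:
        results[label] = response_analysis(averaged, label, config)
        logger.info("analyze[%s]: %d candidates, %d ROC rows", label,
                    len(results[label]["candidates"]), len(results[label]["roc"]))

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(cohort, out / "features.csv", config)
        write_feature_table(averaged, out / "features_rater_mean.csv", config)
        for name, df in (("icc", icc),):
            df.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
            _stamp(out / f"{name}.csv", config)
        for label in config.labels:
            res = results[label]
            for key, df in (
                (f"{label}_response", res["group_tables"]["response"]),
                (f"{label}_paired", res["group_tables"]["paired"]),
                (f"{label}_roc", res["roc"]),
                (f"{label}_delong", res["delong"]),
            ):
                df.to_csv(out / f"{key}.csv", index=False, float_format=_FLOAT_FMT)
                _stamp(out / f"{key}.csv", config)
            for cname, curve in res["curves"].items():
                cpath = out / f"{label}_curve_{cname}.csv"
                curve.to_csv(cpath, index=False, float_format=_FLOAT_FMT)
            if res["curves"]:
                plots.plot_roc_curves(
                    res["curves"], out / f"{label}_roc_curves.png",
                    title=f"{label} reference standard (apparent)",
                )
        plots.plot_paired_boxes(averaged, out / "paired_boxes.png")
        with open(out / "manifest.json", "w") as fh:
            json.dump(
                {"config": asdict(config), "config_hash": config.config_hash(),
                 "n_images": len(images), "n_patients": len(labels)},
                fh, indent=2, default=str,
            )
    logger.info("run_study done (%.2fs)", time.time() - t0)
    return results
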