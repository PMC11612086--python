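"""End-to-end pipeline: simulate -> prepare -> radiomics -> select -> train ->
evaluate -> importance, with a provenance manifest.

Each stage reads its predecessors' artifacts from per-stage subdirectories
under the output directory and writes its own plus a provenance record (the
config hash, the stage seed, and content hashes of every output file).  The
global seed deterministically derives each stage's seed, so a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (CATEGORIES, LabeledCohort, apply_exclusions, balance_images,
                     read_clinical_csv, split_manifest, split_patients)
from .data import SectorDataset
from .evaluation import aggregate_patient, evaluate, roc_auc
from .imaging import SlicePair, prepare_slice_inputs
from .importance import compare_sectors, importance_summary, run_importance
from .radiomics import FEATURE_NAMES, Standardizer, extract_features, select_top_k
from .synthetic import SimConfig, generate_cohort
from .training import TrainConfig, predict_probs, train
from .vvit import SectorSpec, VvitConfig, VvitModel

STAGES = ["simulate", "prepare", "radiomics", "select", "train", "evaluate", "importance"]

# stage seeds are derived from the global seed by fixed offsets
_STAGE_SEED_OFFSET = {s: i + 1 for i, s in enumerate(STAGES)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def default_config(seed: int = 0) -> dict:
    """Desk-scale default configuration (see docs/methods.md)."""
    return {
        "seed": seed,
        "threshold": 10.0,
        "test_fraction": 0.25,
        "crop_size": 64,
        "bin_width": 25.0,
        "n_radiomic": 32,
        "bootstrap_B": 1000,
        "sim": dataclasses.asdict(SimConfig(seed=seed)),
        "model": dataclasses.asdict(VvitConfig(
            patch_dim=128, head_dim=16, n_heads=2, mlp_dim=64, depth=2,
            embed_dim=32, head_hidden_layers=4)),
        "train": dataclasses.asdict(TrainConfig(epochs=50, dropout=0.2,
                                        monitor="validation", seed=seed)),
        "importance": {"n_repeats": 100},
    }


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def _stage_seed(config: dict, stage: str) -> int:
    return (int(config["seed"]) * 1000 + _STAGE_SEED_OFFSET[stage]) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record_stage(outdir: Path, config: dict, stage: str, outputs: Sequence[Path]):
    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "config_hash": config_hash(config), "package_version": __version__, "stages": {}}
    manifest["stages"][stage] = {
        "seed": _stage_seed(config, stage),
        "outputs": {str(p.relative_to(outdir)): (_sha256(p) if p.suffix != ".png" else "figure")
                    for p in outputs},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))


def _require(path: Path, stage: str, produced_by: str):
    if not path.exists():
        raise PipelineError(stage, f"missing dependency {path.name} "
                                   f"(run the '{produced_by}' stage first)")


# ---------------------------------------------------------------------------
# clinical feature encoding
# ---------------------------------------------------------------------------

CLINICAL_SECTORS = {
    "demographics": ["age", "sex", "bmi"],
    "comorbidity": ["pvd", "diabetes", "liver_disease"],
    "habit": ["smoking", "alcohol"],
    "surgical": ["ischemia_time", "blood_loss", "surgery_type", "procedure",
                 "approach", "operative_time"],
}


def encode_clinical(df: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Numeric encodings per clinical sector (categories -> ordinal codes)."""
    out = {}
    for sector, cols in CLINICAL_SECTORS.items():
        mat = np.empty((len(df), len(cols)), dtype=np.float64)
        for j, col in enumerate(cols):
            v = df[col]
            if col in CATEGORIES:
                codes = {c: i for i, c in enumerate(CATEGORIES[col])}
                mat[:, j] = [codes[str(x)] for x in v]
            elif v.dtype == bool or col in ("pvd", "diabetes", "liver_disease"):
                mat[:, j] = v.astype(float)
            else:
                mat[:, j] = v.astype(float)
        out[sector] = mat
    return out


def sector_layout(n_radiomic: int, crop_size: int) -> List[SectorSpec]:
    """The eight-sector input layout: class token, three clinical sectors, the
    surgical sector, selected radiomics, and the two flattened image crops."""
    return [
        SectorSpec("class_token", 0),
        SectorSpec("demographics", 3),
        SectorSpec("comorbidity", 3),
        SectorSpec("habit", 2),
        SectorSpec("surgical", 6),
        SectorSpec("radiomic", n_radiomic),
        SectorSpec("tumor", crop_size * crop_size),
        SectorSpec("kidney_tumor", crop_size * crop_size),
    ]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, outdir: Path) -> List[Path]:
    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(**config["sim"])
    bundle = generate_cohort(sim, seed=_stage_seed(config, "simulate"))
    outputs = []
    clin = d / "clinical.csv"
    bundle.clinical.to_csv(clin, index=False)
    outputs.append(clin)
    idx = d / "image_index.json"
    idx.write_text(json.dumps(bundle.image_index(), indent=0, sort_keys=True))
    outputs.append(idx)
    img_dir = d / "images"
    img_dir.mkdir(exist_ok=True)
    for pid, slices in bundle.images.items():
        path = img_dir / f"{pid}.npz"
        np.savez_compressed(
            path,
            ct=np.stack([s.ct for s in slices]),
            tumor=np.stack([s.tumor_mask for s in slices]),
            kidney=np.stack([s.kidney_mask for s in slices]),
        )
        outputs.append(path)
    return outputs


def _load_slices(outdir: Path, pid: str, stage: str) -> List[SlicePair]:
    path = outdir / "simulate" / "images" / f"{pid}.npz"
    _require(path, stage, "simulate")
    with np.load(path) as z:
        return [SlicePair(ct=z["ct"][k], tumor_mask=z["tumor"][k],
                          kidney_mask=z["kidney"][k], patient_id=pid, slice_index=k)
                for k in range(z["ct"].shape[0])]



def stage_prepare(config: dict, outdir: Path) -> List[Path]:
    d = outdir / "prepare"
    d.mkdir(parents=True, exist_ok=True)
    stage = "prepare"
    clin = outdir / "simulate" / "clinical.csv"
    idx = outdir / "simulate" / "image_index.json"
    _require(clin, stage, "simulate")
    _require(idx, stage, "simulate")
    table = read_clinical_csv(clin)
    image_index = json.loads(idx.read_text())
    cohort, log = apply_exclusions(table, image_index, threshold=config["threshold"])
    seed = _stage_seed(config, stage)
    cohort = balance_images(cohort, rng_seed=seed)
    cohort = split_patients(cohort, test_fraction=config["test_fraction"],
                            rng_seed=seed + 1)
    outputs = []
    log_path = d / "exclusion_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    outputs.append(log_path)
    man = d / "split_manifest.csv"
    split_manifest(cohort).to_csv(man, index=False)
    outputs.append(man)
    usable = d / "usable_slices.json"
    usable.write_text(json.dumps({k: list(map(int, v))
                                  for k, v in cohort.usable_slices.items()},
                                 indent=0, sort_keys=True))
    outputs.append(usable)
    crop = int(config["crop_size"])
    inp_dir = d / "model_inputs"
    inp_dir.mkdir(exist_ok=True)
    for pid in sorted(cohort.patient_ids()):
        slices = _load_slices(outdir, pid, stage)
        keep = cohort.usable_slices[pid]
        tum, kid = [], []
        for k in keep:
            t, kt = prepare_slice_inputs(slices[k], size=crop)
            tum.append(t)
            kid.append(kt)
        path = inp_dir / f"{pid}.npz"
        np.savez_compressed(path, tumor=np.stack(tum), kidney_tumor=np.stack(kid),
                            slice_indices=np.asarray(keep))
        outputs.append(path)
    return outputs


def _read_split(outdir: Path, stage: str):
    man = outdir / "prepare" / "split_manifest.csv"
    _require(man, stage, "prepare")
    df = pd.read_csv(man, dtype={"patient_id": str})
    usable = json.loads((outdir / "prepare" / "usable_slices.json").read_text())
    return df, usable


def stage_radiomics(config: dict, outdir: Path) -> List[Path]:
    d = outdir / "radiomics"
    d.mkdir(parents=True, exist_ok=True)
    stage = "radiomics"
    man, usable = _read_split(outdir, stage)
    rows = []
    for _, r in man.iterrows():
        pid = r["patient_id"]
        slices = _load_slices(outdir, pid, stage)
        for k in usable[pid]:
            s = slices[k]
            fv = extract_features(s.ct, s.tumor_mask, bin_width=config["bin_width"])
            rows.append([pid, k, int(r["label"])] + fv.values.tolist())
    df = pd.DataFrame(rows, columns=["patient_id", "slice_index", "label"] + FEATURE_NAMES)
    path = d / "features.csv"
    df.to_csv(path, index=False)
    return [path]


def stage_select(config: dict, outdir: Path) -> List[Path]:
    d = outdir / "select"
    d.mkdir(parents=True, exist_ok=True)
    stage = "select"
    feat_path = outdir / "radiomics" / "features.csv"
    _require(feat_path, stage, "radiomics")
    man, _ = _read_split(outdir, stage)
    feats = pd.read_csv(feat_path, dtype={"patient_id": str})
    train_ids = set(man.loc[man["split"] == "train", "patient_id"])
    tr = feats[feats["patient_id"].isin(train_ids)]
    sel = select_top_k(tr[FEATURE_NAMES], tr["label"].to_numpy(),
                       k=int(config["n_radiomic"]))
    path = d / "selection.json"
    path.write_text(json.dumps({
        "selected_names": sel.selected_names,
        "f_values": {k: (None if not np.isfinite(v) else v)
                     for k, v in sel.f_values.items()},
    }, indent=2))
    return [path]


def build_datasets(config: dict, outdir: Path, stage: str = "train"):
    """Assemble train/test SectorDatasets from the stage artifacts.

    Clinical and radiomic features are z-scored with training-split statistics
    (frozen for the test split); the windowed image crops are standardized by
    the scalar training-pixel mean/SD per image type.
    """
    man, usable = _read_split(outdir, stage)
    feat_path = outdir / "radiomics" / "features.csv"
    sel_path = outdir / "select" / "selection.json"
    clin_path = outdir / "simulate" / "clinical.csv"
    for p, src in [(feat_path, "radiomics"), (sel_path, "select"), (clin_path, "simulate")]:
        _require(p, stage, src)
    selected = json.loads(sel_path.read_text())["selected_names"]
    feats = pd.read_csv(feat_path, dtype={"patient_id": str})
    clinical = read_clinical_csv(clin_path).set_index("patient_id", drop=False)

    crop = int(config["crop_size"])
    sectors = sector_layout(len(selected), crop)
    split_of = dict(zip(man["patient_id"], man["split"]))
    label_of = dict(zip(man["patient_id"], man["label"]))

    per_split = {"train": [], "test": []}
    feats = feats.set_index(["patient_id", "slice_index"])
    for pid in sorted(split_of):
        inp = outdir / "prepare" / "model_inputs" / f"{pid}.npz"
        _require(inp, stage, "prepare")
        with np.load(inp) as z:
            tum, kid, sidx = z["tumor"], z["kidney_tumor"], z["slice_indices"]
        clin_row = clinical.loc[[pid]]
        enc = encode_clinical(clin_row)
        for pos, k in enumerate(sidx):
            rad = feats.loc[(pid, int(k))][selected].to_numpy(dtype=np.float64)
            per_split[split_of[pid]].append({
                "pid": pid, "label": label_of[pid],
                "demographics": enc["demographics"][0],
                "comorbidity": enc["comorbidity"][0],
                "habit": enc["habit"][0],
                "surgical": enc["surgical"][0],
                "radiomic": rad,
                "tumor": tum[pos].ravel(),
                "kidney_tumor": kid[pos].ravel(),
            })

    def to_arrays(rows):
        X = {"class_token": np.zeros((len(rows), 0))}
        for name in ["demographics", "comorbidity", "habit", "surgical", "radiomic",
                     "tumor", "kidney_tumor"]:
            X[name] = np.stack([r[name] for r in rows])
        y = np.array([r["label"] for r in rows], dtype=int)
        pids = np.array([r["pid"] for r in rows])
        return X, y, pids

    Xtr, ytr, ptr = to_arrays(per_split["train"])
    Xte, yte, pte = to_arrays(per_split["test"])
    # z-score with frozen training statistics
    for name in ["demographics", "comorbidity", "habit", "surgical", "radiomic"]:
        std = Standardizer.fit(Xtr[name])
        Xtr[name] = std.transform(Xtr[name])
        Xte[name] = std.transform(Xte[name])
    for name in ["tumor", "kidney_tumor"]:
        mu, sd = float(Xtr[name].mean()), float(Xtr[name].std()) or 1.0
        Xtr[name] = (Xtr[name] - mu) / sd
        Xte[name] = (Xte[name] - mu) / sd
    return (SectorDataset(sectors, Xtr, ytr, ptr),
            SectorDataset(sectors, Xte, yte, pte))


def stage_train(config: dict, outdir: Path) -> List[Path]:
    d = outdir / "train"
    d.mkdir(parents=True, exist_ok=True)
    train_ds, _ = build_datasets(config, outdir, stage="train")
    model_cfg = VvitConfig(**config["model"])
    model = VvitModel(train_ds.sectors, model_cfg, seed=_stage_seed(config, "train"))
    tcfg = TrainConfig(**{**config["train"], "seed": _stage_seed(config, "train")})
    result = train(model, train_ds, tcfg)
    ckpt = d / "checkpoint.npz"
    model.save(ckpt)
    hist = d / "history.jsonl"
    hist.write_text("\n".join(json.dumps(h) for h in result.history) + "\n")
    summary = d / "train_summary.json"
    summary.write_text(json.dumps({
        "best_epoch": result.best_epoch, "best_accuracy": result.best_accuracy,
        "diverged": result.diverged}, indent=2))
    return [ckpt, hist, summary]


def _predictions(config: dict, outdir: Path, stage: str):
    ckpt = outdir / "train" / "checkpoint.npz"
    _require(ckpt, stage, "train")
    model = VvitModel.load(ckpt)
    _, test_ds = build_datasets(config, outdir, stage=stage)
    probs = predict_probs(model, test_ds)
    voted = probs.mean(axis=1)
    return model, test_ds, probs, voted


def stage_evaluate(config: dict, outdir: Path) -> List[Path]:
    d = outdir / "evaluate"
    d.mkdir(parents=True, exist_ok=True)
    stage = "evaluate"
    model, test_ds, probs, voted = _predictions(config, outdir, stage)
    seed = _stage_seed(config, stage)
    B = int(config.get("bootstrap_B", 1000))
    outputs = []
    preds = (voted >= 0.5).astype(int)
    pred_df = pd.DataFrame({"patient_id": test_ds.patient_ids,
                            "label": test_ds.y, "voted_prob": voted, "pred": preds})
    p_path = d / "predictions.csv"
    pred_df.to_csv(p_path, index=False)
    outputs.append(p_path)

    # image-based analysis (bootstrap over slices)
    rep_img = evaluate(test_ds.y, voted, preds, B=B, seed=seed)
    (d / "metrics_image.json").write_text(json.dumps(rep_img.to_dict(), indent=2))
    outputs.append(d / "metrics_image.json")

    # patient-based analysis (mean prob, majority vote; bootstrap over patients)
    by_pat = {pid: voted[rows] for pid, rows in test_ds.patient_index().items()}
    pat_prob, pat_pred = aggregate_patient(by_pat)
    labels = test_ds.patient_labels()
    pids = sorted(labels)
    yp = np.array([labels[p] for p in pids])
    pp = np.array([pat_prob[p] for p in pids])
    pb = np.array([pat_pred[p] for p in pids])
    rep_pat = evaluate(yp, pp, pb, B=B, seed=seed + 1)
    (d / "metrics_patient.json").write_text(json.dumps(rep_pat.to_dict(), indent=2))
    outputs.append(d / "metrics_patient.json")

    for name, (yy, ss) in {"image": (test_ds.y, voted), "patient": (yp, pp)}.items():
        _, fpr, tpr, thr = roc_auc(yy, ss)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        path = d / f"roc_{name}.csv"
        roc.to_csv(path, index=False)
        outputs.append(path)
    return outputs


def stage_importance(config: dict, outdir: Path) -> List[Path]:
    d = outdir / "importance"
    d.mkdir(parents=True, exist_ok=True)
    stage = "importance"
    model, test_ds, _, _ = _predictions(config, outdir, stage)
    n_rep = int(config.get("importance", {}).get("n_repeats", 100))
    results = run_importance(model, test_ds, n_repeats=n_rep,
                             seed=_stage_seed(config, stage))
    outputs = []
    diffs = pd.DataFrame([(r.sector, i, v) for r in results
                          for i, v in enumerate(r.diffs)],
                         columns=["sector", "repeat", "diff"])
    path = d / "diffs.csv"
    diffs.to_csv(path, index=False)
    outputs.append(path)
    summary = importance_summary(results)
    s_path = d / "summary.json"
    s_path.write_text(summary.to_json(orient="records", indent=2))
    outputs.append(s_path)
    P, stars = compare_sectors(results)
    pp = d / "pairwise_p.csv"
    P.to_csv(pp)
    outputs.append(pp)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 4))
        order = summary["sector"].tolist()
        ax.boxplot([next(r.diffs for r in results if r.sector == s) for s in order],
                   tick_labels=order)
        ax.set_ylabel("accuracy difference (original - permuted)")
        ax.axhline(0.0, color="gray", lw=0.5)
        plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
        fig.tight_layout()
        fig_path = d / "boxplot.png"
        fig.savefig(fig_path, dpi=100)
        plt.close(fig)
        outputs.append(fig_path)
    except Exception:
        pass  # the figure is a convenience artifact
    return outputs


_STAGE_FN = {
    "simulate": stage_simulate,
    "prepare": stage_prepare,
    "radiomics": stage_radiomics,
    "select": stage_select,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "importance": stage_importance,
}


def run_pipeline(config: dict, stages: Sequence[str], outdir) -> Path:
    """Execute the requested stages in canonical order; each stage appends a
    provenance record.  A stage failure halts with a stage-named error and
    earlier outputs are retained."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    for stage in [s for s in STAGES if s in stages]:
        try:
            outputs = _STAGE_FN[stage](config, outdir)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        _record_stage(outdir, config, stage, outputs)
    return outdir / "manifest.json"
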