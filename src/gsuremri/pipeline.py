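"""End-to-end two-stage experiment: simulate -> preprocess -> GSURE denoise ->
train priors / MoDL on noisy vs denoised data -> reconstruct -> evaluate.

The experiment grid mirrors the study design: for every training SNR a GSURE
denoiser is fitted to whitened, normalized, fully sampled synthetic k-space;
generative (EDM) priors and unrolled (MoDL) networks are then trained twice —
on the noisy coil-combined adjoints ("naive") and on the stage-1 denoised
images ("gsure") — and each resulting reconstructor is scored on held-out
cases for every (training SNR, inference SNR, acceleration) cell, with paired
Wilcoxon tests between the naive and gsure variants.

Stages cache their outputs in the run directory keyed by a hash of the
configuration; re-running with an identical config skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .diffusion_prior import (DpsConfig, EdmScoreModel, NoiseSchedule,
                              ScoreTrainConfig, dps_reconstruct,
                              posterior_average, train_score_model)
from .evaluation import ReconReport, anatomy_mask, metrics, paired_comparison
from .forward_model import (MultiCoilKSpace, SenseOperator, apply_adjoint,
                            make_mask)
from .gsure import GsureTrainConfig, denoise_dataset, make_gsure_sample, train_denoiser
from .modl import ModlNetwork, ModlTrainConfig, modl_forward, train_modl
from .synth import CoilMaps, NoiseSpec, make_coil_maps, make_phantom, simulate_kspace

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment"]

METHODS = ("naive-dps", "gsure-dps", "naive-modl", "gsure-modl")


@dataclass
class ExperimentConfig:
    """Full description of one desk-scale experiment."""

    name: str = "toy"
    shape: tuple[int, int] = (32, 32)
    n_coils: int = 4
    n_shapes: int = 5
    n_train: int = 50
    n_test: int = 10
    train_snr_db: list[float] = field(default_factory=lambda: [12.0])
    infer_snr_db: list[float] = field(default_factory=lambda: [12.0])
    accelerations: list[float] = field(default_factory=lambda: [4.0])
    acs_width: int = 6          # fully sampled phase-encode lines in the mask
    acs_norm_size: int = 8      # central k-space block used for normalization
    noise_base_std: float = 0.0125  # raw per-coil noise std (sets native SNR)
    coil_corr: float = 0.2      # neighbor-coil noise correlation
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    enable_gsure: bool = True
    seed: int = 0
    # network / training sizes (tiny by design)
    hidden: int = 16
    n_hidden: int = 2
    gsure_epochs: int = 20
    prior_epochs: int = 20
    modl_epochs: int = 2
    modl_hidden: int | None = None  # denoiser width for MoDL (default: hidden)
    n_unrolls: int = 6
    # DPS inference
    dps_steps: int = 100
    dps_sigma_min: float = 0.004
    dps_sigma_max: float = 10.0
    guidance_base: float = 1.0
    n_posterior: int = 2
    speed_curve_k: list[int] = field(default_factory=lambda: [1, 2, 4])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage bookkeeping: outputs, seeds, wall time, config hash."""

    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, path: str, seconds: float,
               cached: bool = False) -> None:
        self.stages[stage] = dict(path=path, seconds=round(seconds, 3),
                                  cached=cached)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _case_seed(base: int, *keys: int) -> int:
    """Stable derived seed below 2**31."""
    h = hashlib.sha256(np.array([base, *keys], dtype=np.int64).tobytes())
    return int.from_bytes(h.digest()[:4], "little") % (2 ** 31)


def _coil_covariance(cfg: ExperimentConfig) -> np.ndarray:
    """Toeplitz neighbor-correlated coil noise covariance."""
    idx = np.arange(cfg.n_coils)
    corr = cfg.coil_corr ** np.abs(idx[:, None] - idx[None, :])
    return cfg.noise_base_std ** 2 * corr


def _simulate_case(cfg: ExperimentConfig, split: str, i: int):
    """One fully sampled, whitened, normalized case plus its ground truth.

    Pre-whitening mixes coils, so the sensitivity maps are whitened with the
    same L^{-1}, re-normalized to unit RSS, and the RSS weight is absorbed
    into the reference image: y* = F S_wn (x rss) / scale + eta*.
    """
    tag = 0 if split == "train" else 1
    phantom = make_phantom(cfg.shape, cfg.n_shapes,
                           _case_seed(cfg.seed, tag, i, 0))
    maps = make_coil_maps(cfg.shape, cfg.n_coils,
                          _case_seed(cfg.seed, tag, i, 1), normalize=True)
    spec = NoiseSpec(coil_covariance=_coil_covariance(cfg),
                     seed=_case_seed(cfg.seed, tag, i, 2))
    ks = simulate_kspace(phantom, maps, spec)
    cov = preprocess.estimate_noise_covariance(ks, patch=max(4, cfg.shape[0] // 4))
    transform = preprocess.WhiteningTransform.from_covariance(cov)
    white = preprocess.prewhiten(ks, cov)
    maps_w = transform.apply(maps.maps)
    rss = np.sqrt(np.sum(np.abs(maps_w) ** 2, axis=0))
    maps_wn = CoilMaps(maps=maps_w / rss, normalized=True)
    norm, record = preprocess.acs_normalize(white, acs=cfg.acs_norm_size)
    truth = phantom.image * rss / record.scale
    return norm, maps_wn, truth, record


def _stage_data(cfg: ExperimentConfig, outdir: Path, manifest: RunManifest):
    path = outdir / "data.npz"
    t0 = time.time()
    if path.exists():
        z = np.load(path)
        manifest.record("data", str(path), time.time() - t0, cached=True)
        return z
    store: dict[str, np.ndarray] = {}
    for split, n in (("train", cfg.n_train), ("test", cfg.n_test)):
        ks, mp, tr, sig = [], [], [], []
        for i in range(n):
            norm, maps, truth, _ = _simulate_case(cfg, split, i)
            ks.append(norm.data)
            mp.append(maps.maps)
            tr.append(truth)
            sig.append(norm.noise_sigma)
        store[f"{split}_kspace"] = np.stack(ks)
        store[f"{split}_maps"] = np.stack(mp)
        store[f"{split}_truth"] = np.stack(tr)
        store[f"{split}_sigma"] = np.array(sig)
    np.savez(path, **store)
    manifest.record("data", str(path), time.time() - t0)
    return np.load(path)


def _noisy_at_snr(data, split: str, i: int, snr: float,
                  cfg: ExperimentConfig) -> MultiCoilKSpace:
    ks = MultiCoilKSpace(data=data[f"{split}_kspace"][i],
                         noise_sigma=float(data[f"{split}_sigma"][i]))
    tag = 0 if split == "train" else 1
    return preprocess.add_noise_to_snr(
        ks, snr, seed=_case_seed(cfg.seed, 7, tag, i, int(snr * 100)))


def _full_op(data, split: str, i: int) -> SenseOperator:
    maps = CoilMaps(maps=data[f"{split}_maps"][i], normalized=True)
    return SenseOperator(maps=maps, mask=None)


def _stage_gsure(cfg: ExperimentConfig, data, outdir: Path,
                 manifest: RunManifest):
    """Train one denoiser per training SNR; emit denoised + adjoint images."""
    path = outdir / "gsure.npz"
    t0 = time.time()
    if path.exists():
        manifest.record("gsure", str(path), time.time() - t0, cached=True)
        return np.load(path)
    store = {}
    for snr in cfg.train_snr_db:
        samples, adjoints = [], []
        for i in range(cfg.n_train):
            noisy = _noisy_at_snr(data, "train", i, snr, cfg)
            op = _full_op(data, "train", i)
            s = make_gsure_sample(noisy, op)
            samples.append(s)
            adjoints.append(apply_adjoint(op, noisy))
        key = f"snr{snr:g}"
        store[f"adjoint_{key}"] = np.stack(adjoints)
        if cfg.enable_gsure:
            tc = GsureTrainConfig(epochs=cfg.gsure_epochs, hidden=cfg.hidden,
                                  n_hidden=cfg.n_hidden, seed=cfg.seed)
            model = train_denoiser(samples, tc)
            store[f"denoised_{key}"] = np.stack(denoise_dataset(model, samples))
            for j, p in enumerate(model.params):
                store[f"gsure_model_{key}_p{j}"] = p
    np.savez(path, **store)
    manifest.record("gsure", str(path), time.time() - t0)
    return np.load(path)


def _require_gsure(cfg: ExperimentConfig, stage1, key: str) -> np.ndarray:
    name = f"denoised_{key}"
    if name not in stage1:
        raise RuntimeError(
            "GSURE-trained methods were requested but stage 1 (GSURE "
            "denoising) is disabled; enable `enable_gsure` or drop the "
            "gsure-* methods")
    return stage1[name]


def _save_model_params(store: dict, prefix: str, params) -> None:
    for j, p in enumerate(params):
        store[f"{prefix}_p{j}"] = p


def _load_model_params(z, prefix: str, params) -> None:
    for j in range(len(params)):
        params[j][...] = z[f"{prefix}_p{j}"]


def _stage_priors(cfg: ExperimentConfig, data, stage1, outdir: Path,
                  manifest: RunManifest) -> dict:
    """EDM priors per (variant, training SNR)."""
    need = [m for m in cfg.methods if m.endswith("dps")]
    models: dict[tuple[str, float], EdmScoreModel] = {}
    if not need:
        manifest.record("priors", "", 0.0)
        return models
    path = outdir / "priors.npz"
    t0 = time.time()
    cached = path.exists()
    z = np.load(path) if cached else None
    store: dict[str, np.ndarray] = {}
    for snr in cfg.train_snr_db:
        key = f"snr{snr:g}"
        for variant in ("naive", "gsure"):
            if f"{variant}-dps" not in cfg.methods:
                continue
            images = (stage1[f"adjoint_{key}"] if variant == "naive"
                      else _require_gsure(cfg, stage1, key))
            sc = ScoreTrainConfig(epochs=cfg.prior_epochs, hidden=cfg.hidden,
                                  n_hidden=cfg.n_hidden, seed=cfg.seed)
            if cached:
                model = EdmScoreModel(cfg.shape, hidden=cfg.hidden,
                                      n_hidden=cfg.n_hidden,
                                      sigma_data=sc.sigma_data, seed=cfg.seed)
                _load_model_params(z, f"{variant}_{key}", model.params)
            else:
                model = train_score_model(list(images), sc)
                _save_model_params(store, f"{variant}_{key}", model.params)
            models[(variant, snr)] = model
    if not cached:
        np.savez(path, **store)
    manifest.record("priors", str(path), time.time() - t0, cached=cached)
    return models


def _undersample(noisy: MultiCoilKSpace, op_full: SenseOperator, R: float,
                 acs: int, seed: int) -> tuple[MultiCoilKSpace, SenseOperator]:
    mask = make_mask(noisy.data.shape[-2:], R, acs, seed)
    op = SenseOperator(maps=op_full.maps, mask=mask)
    return MultiCoilKSpace(data=noisy.data * mask.pattern, mask=mask,
                           noise_sigma=noisy.noise_sigma), op


def _stage_modl(cfg: ExperimentConfig, data, stage1, outdir: Path,
                manifest: RunManifest) -> dict:
    """MoDL networks per (variant, training SNR, R)."""
    need = [m for m in cfg.methods if m.endswith("modl")]
    models: dict[tuple[str, float, float], ModlNetwork] = {}
    if not need:
        manifest.record("modl", "", 0.0)
        return models
    path = outdir / "modl.npz"
    t0 = time.time()
    cached = path.exists()
    z = np.load(path) if cached else None
    store: dict[str, np.ndarray] = {}
    for snr in cfg.train_snr_db:
        key = f"snr{snr:g}"
        for R in cfg.accelerations:
            for variant in ("naive", "gsure"):
                if f"{variant}-modl" not in cfg.methods:
                    continue
                targets = (stage1[f"adjoint_{key}"] if variant == "naive"
                           else _require_gsure(cfg, stage1, key))
                hidden = cfg.modl_hidden or cfg.hidden
                mc = ModlTrainConfig(n_unrolls=cfg.n_unrolls,
                                     epochs=cfg.modl_epochs,
                                     hidden=hidden, n_hidden=cfg.n_hidden,
                                     seed=cfg.seed)
                tag = f"{variant}_{key}_R{R:g}"
                if cached:
                    net = ModlNetwork(cfg.shape, n_unrolls=cfg.n_unrolls,
                                      hidden=hidden,
                                      n_hidden=cfg.n_hidden, seed=cfg.seed)
                    _load_model_params(z, tag, net.params)
                else:
                    pairs = []
                    for i in range(cfg.n_train):
                        noisy = _noisy_at_snr(data, "train", i, snr, cfg)
                        y, op = _undersample(
                            noisy, _full_op(data, "train", i), R,
                            cfg.acs_width,
                            _case_seed(cfg.seed, 9, i, int(R)))
                        pairs.append((y, op, targets[i]))
                    net = train_modl(pairs, mc)
                    _save_model_params(store, tag, net.params)
                models[(variant, snr, R)] = net
    if not cached:
        np.savez(path, **store)
    manifest.record("modl", str(path), time.time() - t0, cached=cached)
    return models


def _dps_samples(model, y, op, cfg: ExperimentConfig, seed: int,
                 count: int) -> list[np.ndarray]:
    sched = NoiseSchedule(sigma_min=cfg.dps_sigma_min,
                          sigma_max=cfg.dps_sigma_max, n_steps=cfg.dps_steps)
    out = []
    for k in range(count):
        dc = DpsConfig(guidance_base=cfg.guidance_base, schedule=sched,
                       n_posterior_samples=count,
                       seed=_case_seed(seed, k))
        out.append(dps_reconstruct(model, y, op, dc))
    return out


def _stage_reconstruct(cfg: ExperimentConfig, data, priors, modl_nets,
                       outdir: Path, manifest: RunManifest):
    t0 = time.time()
    report = ReconReport()
    speed_rows = []
    for train_snr in cfg.train_snr_db:
        for infer_snr in cfg.infer_snr_db:
            for R in cfg.accelerations:
                for i in range(cfg.n_test):
                    noisy = _noisy_at_snr(data, "test", i, infer_snr, cfg)
                    y, op = _undersample(
                        noisy, _full_op(data, "test", i), R, cfg.acs_width,
                        _case_seed(cfg.seed, 11, i, int(R)))
                    truth = data["test_truth"][i]
                    mask = anatomy_mask(truth)
                    for method in cfg.methods:
                        variant, family = method.split("-")
                        seed = _case_seed(cfg.seed, 13, i, int(R),
                                          int(train_snr), int(infer_snr),
                                          METHODS.index(method))
                        if family == "dps":
                            samples = _dps_samples(
                                priors[(variant, train_snr)], y, op, cfg,
                                seed, cfg.n_posterior)
                            recon, _ = posterior_average(samples)
                            if (method == "gsure-dps" and i < 3
                                    and train_snr == cfg.train_snr_db[0]
                                    and infer_snr == cfg.infer_snr_db[0]
                                    and R == cfg.accelerations[0]):
                                kmax = max(cfg.speed_curve_k)
                                more = samples + _dps_samples(
                                    priors[(variant, train_snr)], y, op, cfg,
                                    _case_seed(seed, 999),
                                    max(0, kmax - len(samples)))
                                for k in cfg.speed_curve_k:
                                    avg, _ = posterior_average(more[:k])
                                    nr, _, _ = metrics(avg, truth, mask)
                                    speed_rows.append(dict(
                                        case=i, k=k, nrmse=nr))
                        else:
                            recon = modl_forward(
                                modl_nets[(variant, train_snr, R)], y, op)
                        nr, ss, ps = metrics(recon, truth, mask)
                        report.add(i, method, train_snr, infer_snr, R,
                                   nr, ss, ps)
    df = report.frame()
    df.to_csv(outdir / "report.csv", index=False)
    speed = pd.DataFrame(speed_rows)
    speed.to_csv(outdir / "speed_curve.csv", index=False)
    manifest.record("reconstruct", str(outdir / "report.csv"),
                    time.time() - t0)
    return report, speed


def _stage_tests(cfg: ExperimentConfig, report: ReconReport,
                 outdir: Path) -> pd.DataFrame:
    """Paired naive-vs-gsure Wilcoxon tests per condition and family."""
    families = sorted({m.split("-")[1] for m in cfg.methods
                       if f"naive-{m.split('-')[1]}" in cfg.methods
                       and f"gsure-{m.split('-')[1]}" in cfg.methods})
    conditions = [(t, s, r) for t in cfg.train_snr_db
                  for s in cfg.infer_snr_db for r in cfg.accelerations]
    n_tests = len(families) * len(conditions) * 3
    rows = []
    for fam in families:
        for (t, s, r) in conditions:
            sub_g = report.subset(method=f"gsure-{fam}", train_snr_db=t,
                                  infer_snr_db=s, R=r)
            sub_n = report.subset(method=f"naive-{fam}", train_snr_db=t,
                                  infer_snr_db=s, R=r)
            res = paired_comparison(sub_g, sub_n, n_tests=max(1, n_tests))
            res["family"] = fam
            res["train_snr_db"] = t
            res["infer_snr_db"] = s
            res["R"] = r
            rows.append(res)
    tests = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    tests.to_csv(outdir / "paired_tests.csv", index=False)
    return tests


STAGES = ("data", "gsure", "priors", "modl", "reconstruct")


def run_experiment(config: ExperimentConfig, outdir,
                   until: str | None = None
                   ) -> tuple[RunManifest, ReconReport | None]:
    """Execute the stage DAG and return the manifest and metric report.

    ``until`` stops after the named stage ("data", "gsure", "priors",
    "modl"); completed stages are cached in ``outdir`` and skipped on
    re-run, so the DAG can be driven stage by stage.
    """
    wanted = set(config.methods)
    unknown = wanted - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not config.enable_gsure and any(m.startswith("gsure") for m in wanted):
        raise RuntimeError(
            "GSURE-trained methods requested but stage 1 (GSURE denoising) "
            "is disabled in the config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        old = RunManifest.load(manifest_path)
        if old.config_hash != cfg_hash:
            for f in outdir.glob("*.npz"):
                f.unlink()  # stale cache from a different config
    manifest = RunManifest(config_hash=cfg_hash, seed=config.seed)
    config.to_yaml(outdir / "config.yaml")

    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")

    def _stop(stage: str) -> bool:
        if until == stage:
            manifest.save(manifest_path)
            return True
        return False

    data = _stage_data(config, outdir, manifest)
    if _stop("data"):
        return manifest, None
    stage1 = _stage_gsure(config, data, outdir, manifest)
    if _stop("gsure"):
        return manifest, None
    priors = _stage_priors(config, data, stage1, outdir, manifest)
    if _stop("priors"):
        return manifest, None
    modl_nets = _stage_modl(config, data, stage1, outdir, manifest)
    if _stop("modl"):
        return manifest, None
    report, speed = _stage_reconstruct(config, data, priors, modl_nets,
                                       outdir, manifest)
    tests = _stage_tests(config, report, outdir)
    manifest.save(manifest_path)

    summary = [f"experiment {config.name} ({cfg_hash})",
               report.aggregate().to_string()]
    if len(tests):
        summary.append(tests.to_string())
    (outdir / "summary.txt").write_text("\n\n".join(summary) + "\n")
    return manifest, report
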