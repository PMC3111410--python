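"""End-to-end pipeline: simulate -> preprocess -> learn -> ... -> decode.

Ties the stages into reproducible runs. Every run takes a
:class:`PipelineConfig` (loadable from YAML), executes the requested
stages in dependency order inside an output directory, writes each
stage's artifact as delimited text, and logs the full parameter echo and
seeds so a run is reproducible from its log alone.

The ``simulate`` stage generates data *from the pipeline's own
generative model*: a ground-truth Gabor filter bank excited by sparse
non-overlapping Dirac impulses, whose superposed windows are strung into
an RR-like interval series around a mean interval. Downstream stages
then recover, characterize, cluster, Gabor-match and spectrally analyze
the filter population, and finally decode a band-limited noise stimulus
from a simulated heart-rate response.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import cluster as clu
from . import decode as dec
from . import gabor as gab
from . import ica
from . import preprocess as pre
from . import scaling as sca
from . import synthetic as syn
from .characterize import characterize_bank
from .containers import FilterBank, RRSeries, Stimulus

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "STAGES"]

STAGES = [
    "simulate",
    "preprocess",
    "learn",
    "characterize",
    "cluster",
    "gabor",
    "scaling",
    "decode",
]

# artifacts each stage requires / produces (within the run directory)
_REQUIRES: Dict[str, List[str]] = {
    "simulate": [],
    "preprocess": ["rr.txt"],
    "learn": ["ensemble.txt"],
    "characterize": ["ica_bank.txt"],
    "cluster": ["properties.tsv"],
    "gabor": ["ica_bank.txt"],
    "scaling": ["ica_bank_raw.txt"],
    "decode": ["ica_bank.txt", "truth_bank.txt", "stimulus.txt"],
}


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Defaults mirror the analysis conditions (256-beat windows,
    full-dimension whitening, log-cosh contrast, VLF/LF/HF band
    partition); the simulation block is sized for a desk-scale run.
    """

    # windowing / learning
    window_len: int = 256
    n_components: Optional[int] = None  # None -> full-dimension whitening
    n_filters: Optional[int] = None     # None -> n_components
    nonlinearity: str = "logcosh"
    ica_tol: float = 1e-4
    ica_max_iter: int = 1000
    # artifact correction
    artifact_window: int = 11
    artifact_factor: float = 4.0
    # band partition of (0, 0.5] cycles/beat
    bands: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in syn.BANDS.items()}
    )
    # simulation block
    sim_n_filters: int = 16
    sim_n_windows: int = 2000
    sim_mean_rr: float = 0.9
    sim_rr_scale: float = 0.05   # amplitude of window fluctuations in seconds
    sim_artifact_rate: float = 0.0
    sim_stimulus_s: float = 1200.0
    sim_decode_filter: int = 0
    sim_decode_noise_db: float = 10.0
    # seeds (all explicit)
    seed_bank: int = 101
    seed_excitations: int = 102
    seed_ica: int = 103
    seed_stimulus: int = 104
    seed_response: int = 105

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        if edges[0][0] != 0.0 or abs(edges[-1][1] - 0.5) > 1e-12:
            raise ValueError("bands must partition (0, 0.5]")
        for (lo1, hi1), (lo2, hi2) in zip(edges[:-1], edges[1:]):
            if abs(hi1 - lo2) > 1e-12:
                raise ValueError("bands must be contiguous")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["bands"] = {k: list(v) for k, v in self.bands.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


class MissingStageError(RuntimeError):
    """A stage was requested without its upstream artifacts."""

    def __init__(self, stage: str, missing: str, producer: str):
        super().__init__(
            f"stage {stage!r} needs {missing!r}, produced by stage {producer!r}; "
            "run that stage first"
        )


def _producer_of(artifact: str) -> str:
    table = {
        "rr.txt": "simulate",
        "truth_bank.txt": "simulate",
        "stimulus.txt": "simulate",
        "ensemble.txt": "preprocess",
        "ica_bank.txt": "learn",
        "ica_bank_raw.txt": "learn",
        "pca_bank.txt": "learn",
        "properties.tsv": "characterize",
    }
    return table.get(artifact, "?")


def _check_inputs(stage: str, outdir: Path) -> None:
    for artifact in _REQUIRES[stage]:
        if not (outdir / artifact).exists():
            raise MissingStageError(stage, artifact, _producer_of(artifact))


def run_pipeline(
    config: PipelineConfig,
    outdir,
    stages: Optional[Sequence[str]] = None,
) -> Path:
    """Execute the requested stages in order; returns the run directory.

    Artifacts are plain text tables inside ``outdir``; ``run.log``
    records the stage sequence, seeds and headline numbers, and
    ``config.yaml`` echoes the full configuration. Identical configs
    (same seeds) produce byte-identical numeric tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in set(stages)]

    config.to_yaml(outdir / "config.yaml")
    log_lines: List[str] = [f"stages: {' '.join(ordered)}"]

    for stage in ordered:
        _check_inputs(stage, outdir)
        _RUNNERS[stage](config, outdir, log_lines)

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


# --------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: PipelineConfig, out: Path, log: List[str]) -> None:
    N = cfg.window_len
    bank = syn.gen_gabor_bank(
        cfg.sim_n_filters, N, freq_lo=max(0.01, 2.0 / N), seed=cfg.seed_bank
    )
    exc = syn.gen_excitations(cfg.sim_n_filters, N, cfg.sim_n_windows, seed=cfg.seed_excitations)
    ens = syn.synthesize_observations(bank, exc)
    flat = ens.data.T.ravel()
    sd = flat.std() or 1.0
    intervals = cfg.sim_mean_rr + cfg.sim_rr_scale * flat / sd
    intervals = np.clip(intervals, 0.2 * cfg.sim_mean_rr, None)
    rr = RRSeries(intervals=intervals, label="generative-model")
    if cfg.sim_artifact_rate > 0:
        rng = np.random.default_rng(cfg.seed_excitations + 7)
        hits = rng.random(intervals.size) < cfg.sim_artifact_rate
        factor = np.where(rng.random(intervals.size) < 0.5, 0.5, 2.0)
        rr = RRSeries(intervals=np.where(hits, intervals * factor, intervals), label=rr.label)
    rr.to_text(out / "rr.txt")
    bank.to_text(out / "truth_bank.txt")
    stim = syn.gen_stimulus(cfg.sim_stimulus_s, seed=cfg.seed_stimulus).resample(1.0)
    stim.to_text(out / "stimulus.txt")
    log.append(
        f"simulate: {len(rr)} beats from {cfg.sim_n_filters} filters x "
        f"{cfg.sim_n_windows} windows (seeds bank={cfg.seed_bank} "
        f"exc={cfg.seed_excitations} stim={cfg.seed_stimulus})"
    )


def _stage_preprocess(cfg: PipelineConfig, out: Path, log: List[str]) -> None:
    rr = pre.read_rr(out / "rr.txt")
    corrected, n_fixed = pre.correct_artifacts(rr, cfg.artifact_window, cfg.artifact_factor)
    ens = pre.segment(corrected, cfg.window_len)
    ens.to_text(out / "ensemble.txt")
    log.append(f"preprocess: {ens.n_windows} windows of {ens.window_len}; {n_fixed} artifacts corrected")


def _stage_learn(cfg: PipelineConfig, out: Path, log: List[str]) -> None:
    from .containers import SegmentEnsemble

    ens = SegmentEnsemble.from_text(out / "ensemble.txt")
    n_comp = cfg.n_components
    if n_comp is None:
        # full-dimension whitening, bounded by the achievable rank
        _, wh_probe = pre.whiten(ens, n_components=1)
        achievable = int(
            np.count_nonzero(wh_probe.all_eigenvalues > 1e-10 * wh_probe.all_eigenvalues[0])
        )
        n_comp = min(ens.window_len, ens.n_windows, achievable)
    Z, wh = pre.whiten(ens, n_components=n_comp)
    n_filters = cfg.n_filters or n_comp
    um = ica.fastica(
        Z,
        n_components=n_filters,
        nonlinearity=cfg.nonlinearity,
        tol=cfg.ica_tol,
        max_iter=cfg.ica_max_iter,
        seed=cfg.seed_ica,
    )
    raw = ica.decoding_filters(um, wh, normalize=False)
    raw.to_text(out / "ica_bank_raw.txt")
    raw.normalize().to_text(out / "ica_bank.txt")
    ica.pca_filters(ens, n=n_filters).to_text(out / "pca_bank.txt")
    log.append(
        f"learn: {n_filters} filters from {n_comp} whitened components, "
        f"{um.n_iter} iterations ({cfg.nonlinearity}, seed={cfg.seed_ica})"
    )


def _stage_characterize(cfg: PipelineConfig, out: Path, log: List[str]) -> None:
    bank = FilterBank.from_text(out / "ica_bank.txt")
    table = characterize_bank(bank)
    table.to_csv(out / "properties.tsv", sep="\t", index=False)
    n_loc = int(table["localized"].sum())
    log.append(f"characterize: {n_loc}/{len(table)} filters spectrally localized")


def _stage_cluster(cfg: PipelineConfig, out: Path, log: List[str]) -> None:
    import pandas as pd

    table = pd.read_csv(out / "properties.tsv", sep="\t")
    loc = table[table["localized"]]
    pts = loc[["center_freq", "bandwidth_3db"]].to_numpy()
    if pts.shape[0] < 3:
        raise RuntimeError("too few localized filters to cluster")
    result = clu.mean_shift(pts)
    ctab = clu.cluster_table(pts, result)
    ctab["index"] = loc["index"].to_numpy()
    ctab.to_csv(out / "clusters.tsv", sep="\t", index=False)
    log.append(
        f"cluster: {result.n_clusters} clusters at bandwidth {result.bandwidth:.4g}"
    )


def _stage_gabor(cfg: PipelineConfig, out: Path, log: List[str]) -> None:
    bank = FilterBank.from_text(out / "ica_bank.txt")
    fits = gab.fit_bank(bank)
    fits.to_csv(out / "gabor_fits.tsv", sep="\t", index=False)
    log.append(f"gabor: median correlation {fits['correlation'].median():.4f}")


def _stage_scaling(cfg: PipelineConfig, out: Path, log: List[str]) -> None:
    import pandas as pd

    bank = FilterBank.from_text(out / "ica_bank_raw.txt")
    # long noise records give the dense frequency grid the log binning needs
    freqs, resp = sca.white_noise_response(
        bank, n_reps=50, segment_len=4096, seed=cfg.seed_ica + 1
    )
    f_lo = max(0.005, 2.0 / cfg.window_len)
    fit = sca.loglog_slope(freqs, resp, f_lo=f_lo, f_hi=0.4)
    pd.DataFrame(
        {"freq": fit.bin_freqs, "power": fit.bin_powers}
    ).to_csv(out / "powerlaw.tsv", sep="\t", index=False)
    (out / "powerlaw_fit.txt").write_text(
        f"slope {fit.slope:.6g}\nintercept {fit.intercept:.6g}\n"
        f"r_squared {fit.r_squared:.6g}\nf_lo {fit.f_lo}\nf_hi {fit.f_hi}\n"
    )
    log.append(f"scaling: log-log slope {fit.slope:.3f} (r^2 {fit.r_squared:.3f})")


def _stage_decode(cfg: PipelineConfig, out: Path, log: List[str]) -> None:
    import pandas as pd

    bank = FilterBank.from_text(out / "ica_bank.txt")
    truth = FilterBank.from_text(out / "truth_bank.txt")
    stim = Stimulus.from_text(out / "stimulus.txt")
    h_true = dec.interpolate_filter(
        truth.filters[cfg.sim_decode_filter], stim.rate_hz, cfg.sim_mean_rr
    )
    target = syn.simulate_response(
        stim, h_true, scale=5.0, noise_db=cfg.sim_decode_noise_db, seed=cfg.seed_response
    )
    fit = dec.best_filter(stim, target, bank, mean_rr=cfg.sim_mean_rr)
    pd.DataFrame(
        {
            "filter_index": [fit.filter_index],
            "scale": [fit.scale],
            "snr_overall_db": [fit.snr_overall_db],
            "accuracy_pct": [fit.accuracy_pct],
            "n_snr_windows": [fit.snr_windows_db.size],
        }
    ).to_csv(out / "decoding.tsv", sep="\t", index=False)
    log.append(
        f"decode: filter {fit.filter_index}, SNR {fit.snr_overall_db:.2f} dB, "
        f"accuracy {fit.accuracy_pct:.1f}%"
    )


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "learn": _stage_learn,
    "characterize": _stage_characterize,
    "cluster": _stage_cluster,
    "gabor": _stage_gabor,
    "scaling": _stage_scaling,
    "decode": _stage_decode,
}


def make_fixtures(outdir, seed: int = 0, scale: str = "tiny") -> Path:
    """Write the standard synthetic fixtures with a manifest.

    ``tiny``: an M=8, N=64, P=500 generative-model set (bank,
    observation ensemble, RR series, stimulus). ``paper``: the
    bias-test ensemble at full scale (N=256 windows, 0.05-wide bands
    tiling 0.01-0.5 cycles/beat).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "scale": scale}

    if scale == "tiny":
        M, N, P = 8, 64, 500
        bank = syn.gen_gabor_bank(M, N, freq_lo=2.0 / N, seed=seed)
        exc = syn.gen_excitations(M, N, P, seed=seed + 1)
        ens = syn.synthesize_observations(bank, exc)
        bank.to_text(outdir / "truth_bank.txt")
        ens.to_text(outdir / "ensemble.txt")
        rr = syn.gen_rr_series(4096, seed=seed + 2)
        rr.to_text(outdir / "rr.txt")
        syn.gen_stimulus(600.0, seed=seed + 3).resample(1.0).to_text(outdir / "stimulus.txt")
        manifest.update({"n_filters": M, "window_len": N, "n_windows": P})
    elif scale == "paper":
        ens = syn.gen_subband_sparse_dataset(n_windows=4096, window_len=256, seed=seed)
        ens.to_text(outdir / "bias_ensemble.txt")
        n_bands = max(1, int(round((0.5 - 0.01) / 0.05)))
        manifest.update(
            {
                "n_windows": 4096,
                "window_len": 256,
                "band_width": 0.05,
                "freq_range": [0.01, 0.5],
                "n_bands": n_bands,
            }
        )
    else:
        raise ValueError("scale must be 'tiny' or 'paper'")

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
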