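"""Pipeline orchestration: simulate → tfr → decompose → permtest → export.

Each stage writes its products into the HDF5 study container together
with a digest of the configuration that produced them; re-running with an
unchanged configuration skips the stage. Stage order, seeds and runtimes
are logged through the standard ``logging`` machinery.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, stage_hash
from .inference import (
    build_model_tensor,
    master_decomposition,
    permutation_test,
    standard_model,
)
from .io import StudyContainer
from .synthdata import make_ground_truth, synth_epochs, synth_tensor5d
from .tfr import induced_tfr

logger = logging.getLogger("tmstensor")

__all__ = ["run_pipeline", "export_tables"]


def _stage(container: StudyContainer, name: str, digest: str, outputs_exist) -> bool:
    """True if the stage must run (hash mismatch or outputs missing)."""
    if container.get_stage_hash(name) == digest and outputs_exist():
        logger.info("stage %s: up to date (hash %s), skipping", name, digest)
        return False
    return True


def run_pipeline(config: RunConfig, container_path: str | Path) -> StudyContainer:
    """Execute the requested stages of the synthetic study end to end.

    With ``config.n_trials > 0`` raw epochs are simulated per
    subject/condition and pushed through the TF chain; otherwise the
    factor-structured 5-way tensor is synthesised directly. Failures halt
    with the failing stage named; completed stages stay in the container.
    """
    container = StudyContainer(container_path, "a")
    contrast = standard_model(config.model_id)
    sim = config.sim
    if tuple(sim.condition_labels) != contrast.condition_labels:
        # the tensor's condition axis must carry the contrast's labels
        from dataclasses import replace as _rep

        sim = _rep(sim, condition_labels=contrast.condition_labels,
                   n_conditions=len(contrast.condition_labels))

    try:
        # -- simulate --------------------------------------------------
        digest = stage_hash("simulate", sim, config.n_trials)
        if _stage(container, "simulate", digest,
                  lambda: "ground_truth" in container.groups()):
            t0 = time.perf_counter()
            gt = make_ground_truth(sim)
            container.write_ground_truth(gt)
            if config.n_trials > 0:
                for s in range(sim.n_subjects):
                    for c, label in enumerate(sim.condition_labels):
                        ep_seed = int(
                            np.random.default_rng(
                                [max(sim.seed, 0), 11, s, c]
                            ).integers(2**31)
                        )
                        epochs = synth_epochs(gt, config.n_trials, ep_seed)
                        container.write_epochs(f"S{s + 1:02d}", label, epochs)
            else:
                tensor = synth_tensor5d(gt, sim)
                container.write_tensor5d(config.model_id, tensor)
            container.set_stage_hash("simulate", digest)
            logger.info("stage simulate: seed=%s, %.2fs", sim.seed,
                        time.perf_counter() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline halted in stage 'simulate': {err}") from err

    try:
        # -- tfr (only on the raw-epochs path) -------------------------
        if config.n_trials > 0:
            digest = stage_hash("tfr", sim, config.tfr, config.n_trials)
            if _stage(container, "tfr", digest,
                      lambda: "tfr" in container.groups()):
                t0 = time.perf_counter()
                for s in range(sim.n_subjects):
                    subject = f"S{s + 1:02d}"
                    for label in sim.condition_labels:
                        epochs = container.read_epochs(subject, label)
                        block = induced_tfr(epochs, config.tfr,
                                            subject=subject, condition=label)
                        container.write_tfr(subject, label, block)
                container.set_stage_hash("tfr", digest)
                logger.info("stage tfr: %.2fs", time.perf_counter() - t0)
            digest5 = stage_hash("tensorise", sim, config.tfr, config.model_id)
            if _stage(container, "tensorise", digest5,
                      lambda: "tensor5d" in container.groups()):
                tensor = build_model_tensor(container, contrast)
                container.write_tensor5d(config.model_id, tensor)
                container.set_stage_hash("tensorise", digest5)
    except Exception as err:
        raise RuntimeError(f"pipeline halted in stage 'tfr': {err}") from err

    try:
        # -- decompose -------------------------------------------------
        digest = stage_hash("decompose", sim, config.decompose, config.model_id,
                            tuple(config.rank_sweep))
        if _stage(container, "decompose", digest,
                  lambda: "models" in container.groups()):
            t0 = time.perf_counter()
            tensor = container.read_tensor5d(config.model_id)
            master = master_decomposition(tensor, config.decompose)
            container.write_model(f"master_model{config.model_id}", master,
                                  seed=config.decompose.seed)
            logger.info("stage decompose: fit=%.2f%%, seed=%s, %.2fs",
                        master.fit_percent, config.decompose.seed,
                        time.perf_counter() - t0)
            container.set_stage_hash("decompose", digest)
    except Exception as err:
        raise RuntimeError(f"pipeline halted in stage 'decompose': {err}") from err

    try:
        # -- permtest --------------------------------------------------
        digest = stage_hash("permtest", sim, config.decompose, config.model_id,
                            config.n_perm, config.perm_scheme, config.seed)
        if _stage(container, "permtest", digest,
                  lambda: "permtest" in container.groups()):
            t0 = time.perf_counter()
            tensor = container.read_tensor5d(config.model_id)
            master = container.read_model(f"master_model{config.model_id}")
            result = permutation_test(
                tensor, master, contrast, n_perm=config.n_perm,
                seed=config.seed, scheme=config.perm_scheme,
            )
            container.write_permtest(config.model_id, result)
            container.set_stage_hash("permtest", digest)
            logger.info("stage permtest: n_perm=%d seed=%d scheme=%s %.2fs",
                        config.n_perm, config.seed, config.perm_scheme,
                        time.perf_counter() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline halted in stage 'permtest': {err}") from err

    return container


def export_tables(container: StudyContainer, out_dir: str | Path) -> list[Path]:
    """Write human-facing CSVs (full float precision) for whatever the
    container holds: factor matrices per mode, permutation summaries, and
    any rank-sweep table stored by the drivers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    groups = container.groups()
    if not groups or groups == ["ground_truth"]:
        raise ValueError(
            f"container holds nothing exportable; groups present: {groups}"
        )

    if "models" in groups:
        for name in container._file["models"]:
            model = container.read_model(name)
            mode_names = ("space", "frequency", "time", "subject", "condition")
            for m, f in enumerate(model.factors):
                label = mode_names[m] if len(model.factors) == 5 else f"mode{m}"
                df = pd.DataFrame(
                    f, columns=[f"component_{r + 1}" for r in range(model.rank)]
                )
                path = out_dir / f"{name}_{label}.csv"
                # %.17g round-trips float64 exactly
                df.to_csv(path, index_label="row", float_format="%.17g")
                written.append(path)

    if "permtest" in groups:
        for model_id in container._file["permtest"]:
            result = container.read_permtest(model_id)
            path = out_dir / f"permtest_model{model_id}.csv"
            result.to_frame().to_csv(path, index=False, float_format="%.17g")
            written.append(path)

    if not written:
        raise ValueError(
            f"no exportable groups among {groups}; expected 'models' or 'permtest'"
        )
    return written
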