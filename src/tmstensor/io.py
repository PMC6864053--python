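"""HDF5 study container.

Single self-describing file holding every stage's products:

    /epochs/{subject}/{condition}     trials × channels × samples
    /tfr/{subject}/{condition}        channels × freqs × times (+ axis vectors)
    /tensor5d/{model_id}              the stacked 5-way tensor
    /models/{name}/mode{0..4}         factor matrices (+ fit/rank/seed attrs)
    /permtest/{model_id}/{contrast}   null samples, observed, p, decisions
    /ground_truth                     generating factors (synthetic runs)

Every dataset carries its axis labels, every stochastic product its seed,
and the file a schema-version attribute checked on open.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .cpd import CPModel, Tensor5D
from .inference import PermutationResult
from .synthdata import GroundTruth
from .tfr import EpochSet, TFRTensor

SCHEMA_VERSION = "tmstensor-container-1"

__all__ = ["StudyContainer", "SCHEMA_VERSION"]


def _write_strings(group: h5py.Group, name: str, values) -> None:
    group.create_dataset(name, data=np.array([str(v) for v in values], dtype=object),
                         dtype=h5py.string_dtype("utf-8"))


def _read_strings(group: h5py.Group, name: str) -> list[str]:
    return [s.decode() if isinstance(s, bytes) else str(s) for s in group[name][()]]


class StudyContainer:
    """Thin typed wrapper around the HDF5 layout above."""

    def __init__(self, path: str | Path, mode: str = "a"):
        self.path = Path(path)
        self._file = h5py.File(self.path, mode)
        if "schema_version" in self._file.attrs:
            found = self._file.attrs["schema_version"]
            if found != SCHEMA_VERSION:
                self._file.close()
                raise ValueError(
                    f"container schema {found!r} does not match expected "
                    f"{SCHEMA_VERSION!r}; refusing to read {self.path}"
                )
        elif mode != "r":
            self._file.attrs["schema_version"] = SCHEMA_VERSION
        else:
            self._file.close()
            raise ValueError(f"{self.path} has no schema_version attribute")

    # -- lifecycle -----------------------------------------------------
    def close(self) -> None:
        self._file.close()

    def __enter__(self) -> "StudyContainer":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- epochs --------------------------------------------------------
    def write_epochs(self, subject: str, condition: str, epochs: EpochSet) -> None:
        g = self._file.require_group(f"epochs/{subject}")
        if condition in g:
            del g[condition]
        d = g.create_dataset(condition, data=epochs.data)
        d.attrs["sampling_rate"] = epochs.sampling_rate
        d.attrs["t_start"] = float(epochs.times[0])
        chan_key = f"{condition}__channels"
        if chan_key in g:
            del g[chan_key]
        _write_strings(g, chan_key, epochs.ch_names)

    def read_epochs(self, subject: str, condition: str) -> EpochSet:
        g = self._file[f"epochs/{subject}"]
        d = g[condition]
        data = d[()]
        fs = float(d.attrs["sampling_rate"])
        t0 = float(d.attrs["t_start"])
        times = t0 + np.arange(data.shape[2]) / fs
        return EpochSet(
            data=data, sampling_rate=fs, times=times,
            ch_names=_read_strings(g, f"{condition}__channels"),
        )

    # -- per-cell TFR tensors -----------------------------------------
    def write_tfr(self, subject: str, condition: str, tfr: TFRTensor) -> None:
        key = f"tfr/{subject}/{condition}"
        if key in self._file:
            del self._file[key]
        g = self._file.create_group(key)
        g.create_dataset("values", data=tfr.values)
        g.create_dataset("freqs", data=np.asarray(tfr.freqs))
        g.create_dataset("times", data=np.asarray(tfr.times))
        _write_strings(g, "channels", tfr.ch_names)
        for k, v in tfr.provenance.items():
            if v is not None and not isinstance(v, (dict, list, tuple)):
                g.attrs[k] = v

    def read_tfr(self, subject: str, condition: str) -> TFRTensor:
        g = self._file[f"tfr/{subject}/{condition}"]
        return TFRTensor(
            values=g["values"][()],
            ch_names=_read_strings(g, "channels"),
            freqs=g["freqs"][()],
            times=g["times"][()],
            provenance=dict(g.attrs),
        )

    def tfr_cells(self):
        """Yield ((subject, condition), TFRTensor) for every stored cell."""
        if "tfr" not in self._file:
            return
        for subject in self._file["tfr"]:
            for condition in self._file[f"tfr/{subject}"]:
                yield (subject, condition), self.read_tfr(subject, condition)

    # -- 5-way tensors -------------------------------------------------
    def write_tensor5d(self, model_id, tensor: Tensor5D) -> None:
        key = f"tensor5d/{model_id}"
        if key in self._file:
            del self._file[key]
        g = self._file.create_group(key)
        g.create_dataset("values", data=tensor.values)
        g.create_dataset("freqs", data=np.asarray(tensor.freqs))
        g.create_dataset("times", data=np.asarray(tensor.times))
        _write_strings(g, "channels", tensor.channels)
        _write_strings(g, "subjects", tensor.subjects)
        _write_strings(g, "conditions", tensor.condition_labels)
        for k, v in tensor.meta.items():
            if isinstance(v, (int, float, str, bool, np.integer, np.floating)):
                g.attrs[k] = v

    def read_tensor5d(self, model_id) -> Tensor5D:
        g = self._file[f"tensor5d/{model_id}"]
        return Tensor5D(
            values=g["values"][()],
            channels=_read_strings(g, "channels"),
            freqs=g["freqs"][()],
            times=g["times"][()],
            subjects=_read_strings(g, "subjects"),
            condition_labels=_read_strings(g, "conditions"),
            meta=dict(g.attrs),
        )

    # -- CP models -----------------------------------------------------
    def write_model(self, name: str, model: CPModel, seed: int | None = None) -> None:
        key = f"models/{name}"
        if key in self._file:
            del self._file[key]
        g = self._file.create_group(key)
        for m, f in enumerate(model.factors):
            g.create_dataset(f"mode{m}", data=f)
        g.attrs["rank"] = model.rank
        g.attrs["fit_percent"] = model.fit_percent
        g.attrs["iterations"] = model.iterations
        g.attrs["converged"] = model.converged
        g.attrs["convention"] = model.convention
        if seed is not None:
            g.attrs["seed"] = seed

    def read_model(self, name: str) -> CPModel:
        g = self._file[f"models/{name}"]
        factors = [g[f"mode{m}"][()] for m in range(len([k for k in g if k.startswith("mode")]))]
        return CPModel(
            factors=factors,
            rank=int(g.attrs["rank"]),
            fit_percent=float(g.attrs["fit_percent"]),
            iterations=int(g.attrs["iterations"]),
            converged=bool(g.attrs["converged"]),
            convention=str(g.attrs["convention"]),
        )

    # -- permutation results -------------------------------------------
    def write_permtest(self, model_id, result: PermutationResult) -> None:
        key = f"permtest/{model_id}"
        if key in self._file:
            del self._file[key]
        g = self._file.create_group(key)
        g.create_dataset("observed", data=result.observed)
        g.create_dataset("null", data=result.null)
        g.create_dataset("pvalues", data=result.pvalues)
        g.create_dataset("decisions", data=result.decisions)
        g.create_dataset("quantiles", data=result.quantiles)
        _write_strings(g, "contrast_names", result.contrast_names)
        g.attrs["n_perm"] = result.n_perm
        g.attrs["seed"] = result.seed
        g.attrs["scheme"] = result.scheme

    def read_permtest(self, model_id) -> PermutationResult:
        g = self._file[f"permtest/{model_id}"]
        return PermutationResult(
            contrast_names=_read_strings(g, "contrast_names"),
            observed=g["observed"][()],
            null=g["null"][()],
            pvalues=g["pvalues"][()],
            decisions=g["decisions"][()].astype(bool),
            quantiles=g["quantiles"][()],
            n_perm=int(g.attrs["n_perm"]),
            seed=int(g.attrs["seed"]),
            scheme=str(g.attrs["scheme"]),
        )

    # -- ground truth --------------------------------------------------
    def write_ground_truth(self, gt: GroundTruth) -> None:
        if "ground_truth" in self._file:
            del self._file["ground_truth"]
        g = self._file.create_group("ground_truth")
        for name, arr in zip(
            ("space", "frequency", "time", "subject", "condition"),
            gt.factor_list(),
        ):
            g.create_dataset(name, data=arr)
        g.create_dataset("effect", data=gt.effect)
        g.create_dataset("freqs", data=np.asarray(gt.freqs))
        g.create_dataset("times_ms", data=np.asarray(gt.times_ms))
        _write_strings(g, "channels", gt.channels)
        _write_strings(g, "condition_labels", gt.condition_labels)
        g.attrs["noise_sigma"] = gt.noise_sigma
        if "seed" in gt.meta:
            g.attrs["seed"] = gt.meta["seed"]

    def read_ground_truth(self) -> GroundTruth:
        g = self._file["ground_truth"]
        return GroundTruth(
            space_factors=g["space"][()],
            freq_factors=g["frequency"][()],
            time_factors=g["time"][()],
            subject_loadings=g["subject"][()],
            condition_loadings=g["condition"][()],
            condition_labels=tuple(_read_strings(g, "condition_labels")),
            effect=g["effect"][()],
            noise_sigma=float(g.attrs["noise_sigma"]),
            channels=_read_strings(g, "channels"),
            freqs=g["freqs"][()],
            times_ms=g["times_ms"][()],
            meta={"seed": int(g.attrs["seed"])} if "seed" in g.attrs else {},
        )

    # -- bookkeeping ---------------------------------------------------
    def groups(self) -> list[str]:
        return sorted(self._file.keys())

    def set_stage_hash(self, stage: str, digest: str) -> None:
        self._file.attrs[f"hash_{stage}"] = digest

    def get_stage_hash(self, stage: str) -> str | None:
        value = self._file.attrs.get(f"hash_{stage}")
        return None if value is None else str(value)
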