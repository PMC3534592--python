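"""Text-file interchange formats and the EIDORS MAT-file reader.

Datasets live in a directory of delimited-text matrices (rows = electrodes,
columns = patterns) plus a YAML metadata sidecar:

    currents.csv, voltages.csv            the measurement frame
    currents_ref.csv, voltages_ref.csv    the homogeneous reference frame
    meta.yaml                             layout, amplitudes, noise, seed

All round trips are lossless at double precision (`%.17g`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from dbareit.forward_sim import CurrentPatternSet, ElectrodeLayout, VoltageDataset
from dbareit.scattering import KGrid, ScatteringTransform
from dbareit.sinc_dbar import ConductivityImage

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_delta_dn",
    "read_delta_dn",
    "write_scattering",
    "read_scattering",
    "write_image",
    "read_image",
    "read_eidors_frames",
]

_FMT = "%.17g"


def _save(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt=_FMT, delimiter=",")


def _load(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing data file: {path}")
    return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))


def write_dataset(
    dirpath: str | Path,
    dataset: VoltageDataset,
    reference: VoltageDataset | None = None,
    extra_meta: dict | None = None,
) -> Path:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    _save(d / "currents.csv", dataset.patterns.T)
    _save(d / "voltages.csv", dataset.V)
    if reference is not None:
        _save(d / "currents_ref.csv", reference.patterns.T)
        _save(d / "voltages_ref.csv", reference.V)
    lay = dataset.layout
    meta = {
        "L": lay.L,
        "r": lay.r,
        "A": lay.A,
        "height": lay.height,
        "z_contact": lay.z_contact,
        "M": dataset.patterns.M,
        "noise_seed": dataset.noise_seed,
        "noise_amplitude": dataset.noise_amplitude,
        "noise_target": dataset.noise_target,
        "protocol": "trigonometric",
    }
    if extra_meta:
        meta.update(extra_meta)
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return d


def read_dataset(
    dirpath: str | Path,
) -> tuple[VoltageDataset, VoltageDataset | None, dict]:
    """Load a dataset directory -> (measurement, reference or None, meta)."""
    d = Path(dirpath)
    meta_path = d / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file: {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    lay = ElectrodeLayout(
        L=int(meta["L"]), r=float(meta["r"]), A=float(meta["A"]),
        height=float(meta.get("height", 1.0)),
        z_contact=float(meta["z_contact"]),
    )
    T = _load(d / "currents.csv")
    V = _load(d / "voltages.csv")
    ds = VoltageDataset(
        V=V,
        patterns=CurrentPatternSet(T=T, M=float(meta["M"])),
        layout=lay,
        noise_seed=meta.get("noise_seed"),
        noise_amplitude=float(meta.get("noise_amplitude", 0.0)),
        noise_target=meta.get("noise_target", "currents"),
    )
    ref = None
    if (d / "voltages_ref.csv").exists():
        Tr = _load(d / "currents_ref.csv")
        Vr = _load(d / "voltages_ref.csv")
        ref = VoltageDataset(
            V=Vr, patterns=CurrentPatternSet(T=Tr, M=float(meta["M"])), layout=lay
        )
    return ds, ref, meta


def write_delta_dn(path: str | Path, dL: np.ndarray, meta: dict) -> None:
    p = Path(path)
    _save(p, dL)
    p.with_suffix(p.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_delta_dn(path: str | Path) -> tuple[np.ndarray, dict]:
    p = Path(path)
    dL = _load(p)
    meta = json.loads(p.with_suffix(p.suffix + ".meta.json").read_text())
    return dL, meta


def write_scattering(dirpath: str | Path, t: ScatteringTransform) -> Path:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    _save(d / "t_real.csv", t.values.real)
    _save(d / "t_imag.csv", t.values.imag)
    _save(d / "k_real.csv", t.grid.points.real)
    _save(d / "k_imag.csv", t.grid.points.imag)
    (d / "grid.json").write_text(
        json.dumps({"R": t.grid.R, "gamma_best": t.gamma_best})
    )
    return d


def read_scattering(dirpath: str | Path) -> ScatteringTransform:
    d = Path(dirpath)
    info = json.loads((d / "grid.json").read_text())
    pts = _load(d / "k_real.csv") + 1j * _load(d / "k_imag.csv")
    vals = _load(d / "t_real.csv") + 1j * _load(d / "t_imag.csv")
    return ScatteringTransform(
        values=vals, grid=KGrid(R=info["R"], points=pts),
        gamma_best=info["gamma_best"],
    )


def write_image(
    dirpath: str | Path, img: ConductivityImage, png: bool = True
) -> Path:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    _save(d / "gamma.csv", img.gamma)
    _save(d / "converged.csv", img.converged.astype(int))
    (d / "meta.json").write_text(json.dumps(img.meta, indent=1, default=float))
    if png:
        render_image(img, d / "gamma.png")
    return d


def read_image(dirpath: str | Path) -> ConductivityImage:
    d = Path(dirpath)
    gamma = _load(d / "gamma.csv")
    conv = _load(d / "converged.csv").astype(bool)
    meta = json.loads((d / "meta.json").read_text())
    n = gamma.shape[0]
    ax = np.linspace(-1, 1, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    pts = X + 1j * Y
    return ConductivityImage(
        points=pts, mask=np.isfinite(gamma), gamma=gamma, converged=conv, meta=meta
    )


def render_image(img: ConductivityImage, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4))
    im = ax.imshow(
        img.gamma.T, origin="lower", extent=(-1, 1, -1, 1), cmap="viridis"
    )
    fig.colorbar(im, ax=ax, label="conductivity")
    ax.set_xlabel("x1")
    ax.set_ylabel("x2")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def read_eidors_frames(path: str | Path) -> tuple[VoltageDataset, dict]:
    """Best-effort ingestion of EIDORS-style MAT-file dumps.

    Looks for a current-pattern array and a voltage array of matching shape.
    Trigonometric patterns are detected by column-sum and orthogonality
    checks; anything else is loaded but flagged ``protocol='unknown'`` (the
    D-bar chain requires trigonometric patterns and refuses other frames).
    """
    from scipy.io import loadmat

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing MAT-file: {p}")
    try:
        raw = loadmat(p)
    except Exception as exc:
        raise ValueError(f"cannot parse MAT-file {p}: {exc}") from exc
    arrays = {
        k: np.asarray(v, dtype=float)
        for k, v in raw.items()
        if not k.startswith("__") and np.ndim(v) == 2 and min(np.shape(v)) > 1
    }
    cur_keys = [k for k in arrays if "current" in k.lower() or k.lower() in ("t", "cp")]
    volt_keys = [k for k in arrays if "volt" in k.lower() or k.lower() in ("v", "u")]
    if not cur_keys or not volt_keys:
        raise ValueError(
            f"MAT-file {p} lacks recognizable current/voltage arrays "
            f"(found: {sorted(arrays)})"
        )
    T = arrays[cur_keys[0]]
    V = arrays[volt_keys[0]]
    if T.shape[0] < T.shape[1]:
        pass
    elif T.shape[1] == V.shape[1] and T.shape[0] == V.shape[0]:
        pass
    else:
        V = V.reshape(T.shape[0], -1)[:, : T.shape[1]]
    if T.shape != V.shape:
        raise ValueError(f"current {T.shape} / voltage {V.shape} shape mismatch")
    L = T.shape[0]
    # trig detection: zero column sums and near-orthogonal normalized columns
    sums_ok = np.max(np.abs(T.sum(axis=0))) < 1e-6 * np.abs(T).max()
    tn = T / np.linalg.norm(T, axis=0)
    gram = tn.T @ tn
    ortho_ok = np.max(np.abs(gram - np.eye(T.shape[1]))) < 1e-3
    protocol = "trigonometric" if (sums_ok and ortho_ok and T.shape[1] == L - 1) else "unknown"
    layout = ElectrodeLayout(L=L if L % 2 == 0 else L + 1)
    ds = VoltageDataset(
        V=V - V.mean(axis=0),
        patterns=CurrentPatternSet(T=T, M=float(np.abs(T).max())),
        layout=layout,
    )
    return ds, {"protocol": protocol, "source": str(p)}
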