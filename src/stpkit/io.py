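"""Readers and writers for the interchange formats used by the pipeline.

Sweeps travel as HDF5 (one group per connection: ``pre``/``post``/``time``
arrays plus JSON-encoded metadata) or flat CSV; connection records and
feature tables as CSV with documented column names; image volumes as
multi-page TIFF.  An NWB reader stub is provided for the deposit's stated
future format.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .extraction import ConnectionRecord, EPSPFeatures
from .metrics import DynamicsHeatmap, records_to_frame
from .protocols import StimProtocol
from .sweeps import SweepSet


def save_sweeps_h5(path: str | Path, sweep_sets: dict[str, SweepSet]) -> None:
    with h5py.File(path, "w") as f:
        for name, s in sweep_sets.items():
            g = f.create_group(name)
            g.create_dataset("time", data=s.time)
            g.create_dataset("v_pre", data=s.v_pre)
            g.create_dataset("v_post", data=s.v_post)
            g.create_dataset("stim_times", data=s.stim_times)
            meta = dict(
                sampling_rate=s.sampling_rate,
                frequency=s.protocol.frequency,
                n_induction=s.protocol.n_induction,
                n_recovery=s.protocol.n_recovery,
                recovery_delay=s.protocol.recovery_delay,
                inter_sweep_interval=s.protocol.inter_sweep_interval,
                n_sweeps=s.protocol.n_sweeps,
                **s.metadata,
            )
            g.attrs["metadata"] = json.dumps(meta)


def load_sweeps_h5(path: str | Path) -> dict[str, SweepSet]:
    out: dict[str, SweepSet] = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            meta = json.loads(g.attrs["metadata"])
            protocol = StimProtocol(
                frequency=meta.pop("frequency"),
                n_induction=meta.pop("n_induction"),
                n_recovery=meta.pop("n_recovery"),
                recovery_delay=meta.pop("recovery_delay"),
                inter_sweep_interval=meta.pop("inter_sweep_interval"),
                n_sweeps=meta.pop("n_sweeps"),
            )
            out[name] = SweepSet(
                time=g["time"][:],
                v_pre=g["v_pre"][:],
                v_post=g["v_post"][:],
                stim_times=g["stim_times"][:],
                protocol=protocol,
                sampling_rate=meta.pop("sampling_rate"),
                metadata=meta,
            )
    return out


def sweeps_to_csv(sweeps: SweepSet, path: str | Path, sweep_index: int = 0) -> None:
    """Flat (time, v_pre, v_post) CSV of one sweep."""
    pd.DataFrame(
        dict(
            time=sweeps.time,
            v_pre=sweeps.v_pre[sweep_index],
            v_post=sweeps.v_post[sweep_index],
        )
    ).to_csv(path, index=False)


def save_records_csv(records: list[ConnectionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def load_records_csv(path: str | Path) -> list[ConnectionRecord]:
    df = pd.read_csv(path)
    amp_cols = sorted(
        (c for c in df.columns if c.startswith("amp_")),
        key=lambda c: int(c.split("_")[1]),
    )
    records = []
    for _, row in df.iterrows():
        feats = None
        if "epsp_amplitude" in row and np.isfinite(row.get("epsp_amplitude", np.nan)):
            feats = EPSPFeatures(
                amplitude=row["epsp_amplitude"],
                onset_delay=row.get("epsp_onset_ms", np.nan),
                rise_time=row.get("epsp_rise_ms", np.nan),
                decay_tau=row.get("epsp_decay_tau_ms", np.nan),
                fit_quality=np.nan,
            )
        records.append(
            ConnectionRecord(
                connection_id=str(row["connection_id"]),
                amplitudes=row[amp_cols].to_numpy(float),
                frequency=row["frequency"],
                recovery_delay=row["recovery_delay_ms"] / 1e3,
                first_epsp=feats,
                prep=row["prep"],
                disease=row["disease"],
                div=row.get("div", np.nan),
                postsynaptic=row.get("postsynaptic", "unknown"),
            )
        )
    return records


def save_volume_tiff(path: str | Path, stack: np.ndarray) -> None:
    """(n_channels, z, y, x) stack as a multi-page TIFF (CZYX order)."""
    tifffile.imwrite(
        path,
        np.asarray(stack, np.float32),
        photometric="minisblack",
        metadata={"axes": "CZYX"},
    )


def load_volume_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def export_heatmap(
    hm: DynamicsHeatmap, csv_path: str | Path, png_path: str | Path | None = None
) -> None:
    df = pd.DataFrame(
        hm.matrix,
        index=hm.connection_ids,
        columns=[f"pulse_{k + 1}" for k in range(hm.matrix.shape[1])],
    )
    df.to_csv(csv_path, index_label="connection_id")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(hm.matrix, aspect="auto", cmap="viridis", vmin=0, vmax=2)
        ax.set_xlabel("pulse")
        ax.set_ylabel("connection (sorted by EPSP amplitude)")
        title = f"{hm.frequency:g} Hz"
        if hm.prep:
            title += f", {hm.prep}"
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="amplitude / pulse 1")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def load_nwb_stub(path: str | Path):
    """Placeholder reader for NWB-format connectivity assays.

    The deposited recordings are slated for NWB release; this hook exists so
    the extraction pipeline gains a real reader without interface changes.
    """
    raise NotImplementedError(
        "NWB reading is not implemented; convert to the HDF5 sweep format"
    )
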