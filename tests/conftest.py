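import numpy as np
import pytest

from tfcrscreen import (
    SyntheticConfig,
    bin_tfcrs,
    generate_landscape,
    identify_tfcrs,
)
from tfcrscreen import io as gio
from tfcrscreen.models import Tfcr, TfbsRecord


@pytest.fixture(scope="session")
def default_landscape(tmp_path_factory):
    """The standard synthetic benchmark: 200 clusters, seed 17."""
    out = tmp_path_factory.mktemp("landscape")
    return generate_landscape(SyntheticConfig(), out)


@pytest.fixture(scope="session")
def called_default(default_landscape):
    """TFCRs called from the standard landscape files, decile-binned."""
    truth = default_landscape
    called = {}
    for cond in ("tumor", "normal"):
        tfbs = gio.read_fimo_hits(truth.files[f"tfbs_{cond}"])
        peaks = gio.read_narrowpeak(
            truth.files[f"peaks_{cond}"],
            source="ATAC" if cond == "tumor" else "DNase",
            condition=cond,
        )
        tfcrs = identify_tfcrs(tfbs, peaks, truth.config.analysis_params, cond)
        bin_tfcrs(tfcrs)
        called[cond] = tfcrs
    return truth, called


@pytest.fixture()
def small_config():
    """A fast landscape for pipeline/CLI integration tests."""
    return SyntheticConfig(
        seed=3,
        n_chrom=1,
        chrom_length=400_000,
        n_shared=10,
        n_gain=5,
        n_lost=5,
        n_genes=30,
        n_driver_genes=2,
        cluster_tc_mean=20.0,
    )


def make_tfbs(chrom, positions, tf_names=None, width=10):
    """Build TFBS records with midpoints at the given positions."""
    half = width // 2
    out = []
    for i, pos in enumerate(positions):
        name = tf_names[i] if tf_names is not None else f"TF{i:03d}"
        out.append(
            TfbsRecord(chrom=chrom, start=pos - half, end=pos + width - half,
                       tf_name=name)
        )
    return out


def make_tfcr(tfcr_id, chrom, ws, we, tc=1, sc=0.0, condition="tumor",
              tc_bin=None, sc_bin=None, summit=None):
    return Tfcr(
        tfcr_id=tfcr_id,
        chrom=chrom,
        summit=summit if summit is not None else (ws + we) // 2,
        window_start=ws,
        window_end=we,
        tc=tc,
        sc=sc,
        condition=condition,
        tc_bin=tc_bin,
        sc_bin=sc_bin,
    )


def brute_force_density(midpoints, grid_start, n_points, sigma, step=1):
    """Per-bp oracle: full (untruncated) kernel summation."""
    x = grid_start + step * np.arange(n_points, dtype=np.int64)
    dens = np.zeros(n_points)
    for m in midpoints:
        dens += np.exp(-((x - m) ** 2) / (2.0 * sigma**2))
    return dens


def brute_force_maxima(values, floor=1e-6):
    """Independent plateau-aware local-maximum scanner (index of plateau mid).

    The floor mirrors the caller's numerical guard: genuine maxima of
    unit-height kernel sums always exceed exp(-1/2), while float jitter in
    far tails can fabricate maxima at ~1e-13 density.
    """
    idx = []
    n = len(values)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if (
            values[i] > values[i - 1]
            and j + 1 < n
            and values[i] > values[j + 1]
            and values[i] >= floor
        ):
            idx.append((i + j) // 2)
        i = j + 1
    return idx
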