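"""Report figures: grand-average MRCP comparison and ERDS panels."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_mrcp_comparison(cued, self_paced, channel_index: int,
                         channel_name: str, stat=None, path=None):
    """Grand-average MRCPs of both conditions with SE bands; samples with
    a significant condition difference are shaded."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for epochs, color, label in ((cued, "tab:orange", "cue-based"),
                                 (self_paced, "tab:red", "self-paced")):
        data = epochs.data[:, channel_index, :]
        mean = data.mean(axis=0)
        se = data.std(axis=0, ddof=1) / np.sqrt(epochs.n_trials)
        ax.plot(epochs.times, mean, color=color, label=label)
        ax.fill_between(epochs.times, mean - se, mean + se, color=color,
                        alpha=0.3, lw=0)
    if stat is not None:
        sig = stat.significant[channel_index]
        n = len(sig)
        t_sig = np.linspace(cued.times[0], cued.times[-1], n)[sig]
        for t in t_sig:
            ax.axvspan(t - 0.01, t + 0.01, color="gray", alpha=0.4, lw=0)
    ax.axvline(0, color="k", ls="--", lw=0.8)
    ax.set_xlabel("time relative to movement onset (s)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title(f"grand-average MRCP, {channel_name}")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_erds_map(erds, channel_name: str, path=None):
    """ERDS map (percent band-power change); non-significant pixels dimmed."""
    fig, ax = plt.subplots(figsize=(6, 4))
    vmax = max(1.0, np.abs(erds.values).max())
    shown = np.where(erds.significant, erds.values, np.nan)
    mesh = ax.pcolormesh(erds.times, erds.freqs, erds.values, cmap="RdBu",
                         vmin=-vmax, vmax=vmax, alpha=0.35, shading="auto")
    ax.pcolormesh(erds.times, erds.freqs, shown, cmap="RdBu",
                  vmin=-vmax, vmax=vmax, shading="auto")
    fig.colorbar(mesh, ax=ax, label="power change vs. reference (%)")
    ax.axvline(0, color="k", ls="--", lw=0.8)
    ax.set_xlabel("time relative to movement onset (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"ERDS, {channel_name}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
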