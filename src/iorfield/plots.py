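"""Optional plotting of sweep outputs (IOR curve, habituation curve)."""

from __future__ import annotations

from pathlib import Path

from .protocols import HabituationCurve, IORCurve


def plot_ior_curve(curve: IORCurve, path: str | Path, title: str = "") -> None:
    """Mean RT per CTOA for cued and uncued trials, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.ctoas, curve.rt_cued, "o-", color="k", label="cued")
    ax.plot(curve.ctoas, curve.rt_uncued, "o--", mfc="white", color="k", label="uncued")
    ax.set_xlabel("CTOA (ms)")
    ax.set_ylabel("RT (ms)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_habituation_curve(
    curve: HabituationCurve, path: str | Path, title: str = ""
) -> None:
    """Peak target-induced sensory rate against CTOA, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.ctoas, curve.peak_rate, color="k")
    ax.set_xlabel("CTOA (ms)")
    ax.set_ylabel("peak a_S at target locus")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
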