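"""Quick-look plots (optional; requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

from .pde import ReleaseCurve


def plot_release_curve(curve: ReleaseCurve, path: str | Path) -> Path:
    """Save a two-panel PNG: released fraction and release rate vs log time."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax_f, ax_r) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    label = (
        f"K={curve.params.K:g}, G={curve.params.G:g}, n={curve.params.n:g}"
    )
    ax_f.semilogx(curve.tau, curve.fraction_released, label=label)
    ax_f.set_ylabel("fraction released")
    ax_f.legend(frameon=False)
    ax_r.loglog(curve.tau, curve.rate)
    ax_r.set_xlabel(r"dimensionless time $\tau$")
    ax_r.set_ylabel(r"release rate $dF/d\tau$")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
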