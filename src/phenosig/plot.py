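"""Minimal dot-plot helper for auxotrophy signatures."""
from __future__ import annotations

from .profiling import CommunitySignature


def auxotrophy_dotplot(signatures: list[CommunitySignature], ax=None):
    """Per-vitamin dots of auxotrophy %, one point per sample, colored by
    group. Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    vitamins = list(signatures[0].auxotrophy.index)
    groups = sorted({s.group_label or "" for s in signatures})
    cmap = plt.get_cmap("tab10")
    colors = {g: cmap(i % 10) for i, g in enumerate(groups)}
    for gi, g in enumerate(groups):
        members = [s for s in signatures if (s.group_label or "") == g]
        for vi, v in enumerate(vitamins):
            x = [vi + (gi - (len(groups) - 1) / 2) * 0.18] * len(members)
            ax.plot(x, [s.auxotrophy[v] for s in members], "o", ms=4,
                    color=colors[g], label=g if vi == 0 else None)
    ax.set_xticks(range(len(vitamins)), vitamins)
    ax.set_ylabel("auxotrophy representation (%)")
    ax.legend(title="group", fontsize=8)
    return ax
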