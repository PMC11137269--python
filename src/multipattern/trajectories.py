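"""Multimorbidity trajectories: linking wave-specific patterns over time.

Patterns are re-derived independently at each wave, so trajectories are
flows of patients between wave-specific cluster labels, with two absorbing
states — Death and Lost (to follow-up) — for patients leaving the closed
cohort.  The flow table feeds an alluvial plot whose box and stripe sizes
are proportional to patient counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import DEAD, INCLUDED, LOST, WAVES, PatientRecord
from .errors import InconsistencyError

DEATH_NODE = "Death"
LOST_NODE = "Lost"
ABSORBING = (DEATH_NODE, LOST_NODE)


def pattern_node(index: int) -> str:
    return f"P{index}"


@dataclass
class TrajectoryTable:
    """Counts of patients flowing between wave-specific nodes.

    Nodes are pattern labels (``P0`` ...) plus the absorbing ``Death`` and
    ``Lost`` states at post-baseline waves.  Absorbing nodes never flow
    onward.
    """

    waves: tuple[str, ...]
    nodes: dict[str, tuple[str, ...]]                       # wave -> node names
    flows: dict[tuple[str, str, str, str], int]
    # (wave_from, node_from, wave_to, node_to) -> count

    @classmethod
    def from_flows(
        cls, flows: Mapping[tuple[str, str, str, str], int]
    ) -> "TrajectoryTable":
        waves = sorted({wf for wf, _, _, _ in flows} | {wt for _, _, wt, _ in flows})
        nodes: dict[str, set[str]] = {w: set() for w in waves}
        for wf, nf, wt, nt in flows:
            nodes[wf].add(nf)
            nodes[wt].add(nt)

        def order(names: set[str]) -> tuple[str, ...]:
            patterns = sorted(n for n in names if n not in ABSORBING)
            tail = [n for n in ABSORBING if n in names]
            return tuple(patterns + tail)

        return cls(
            waves=tuple(waves),
            nodes={w: order(s) for w, s in nodes.items()},
            flows={k: int(v) for k, v in flows.items() if v},
        )

    def node_size(self, wave: str, node: str) -> int:
        """Outflow for the first wave's nodes, inflow otherwise."""
        if wave == self.waves[0]:
            return sum(
                c for (wf, nf, _, _), c in self.flows.items()
                if wf == wave and nf == node
            )
        return sum(
            c for (_, _, wt, nt), c in self.flows.items()
            if wt == wave and nt == node
        )

    def outflow(self, wave: str, node: str) -> int:
        return sum(
            c for (wf, nf, _, _), c in self.flows.items()
            if wf == wave and nf == node
        )

    def count(self, wave_from: str, node_from: str, wave_to: str, node_to: str) -> int:
        return self.flows.get((wave_from, node_from, wave_to, node_to), 0)


def _absorbing_target(patient: PatientRecord, after: str, upto: str) -> str:
    """First Death/Lost event strictly after wave `after`, up to `upto`."""
    i, j = WAVES.index(after), WAVES.index(upto)
    for wave in WAVES[i + 1 : j + 1]:
        st = patient.status(wave)
        if st == DEAD:
            return DEATH_NODE
        if st == LOST:
            return LOST_NODE
    raise InconsistencyError(
        f"patient {patient.patient_id}: no label at {upto} yet status is "
        f"'included' at every wave up to it"
    )


def link_waves(
    results: Mapping[str, "ClusteringResult"],
    patients: Sequence[PatientRecord] | Mapping[str, PatientRecord],
    waves: Sequence[str] | None = None,
) -> TrajectoryTable:
    """Tabulate pattern-to-pattern flows between consecutive given waves.

    Passing non-adjacent waves (e.g. baseline and the final wave) yields the
    endpoint table; deaths and losses in between route to the absorbing node
    of the patient's first event.  A patient labelled at a wave where their
    status is dead/lost is a consistency error.
    """
    if isinstance(patients, Mapping):
        by_id = dict(patients)
    else:
        by_id = {p.patient_id: p for p in patients}
    if waves is None:
        waves = sorted(results, key=WAVES.index)
    waves = tuple(waves)
    label_maps: dict[str, dict[str, int]] = {}
    for w in waves:
        # a wave with no clustering result (e.g. fully attrited) has no labels
        label_maps[w] = results[w].labels_by_id() if w in results else {}
        for pid in label_maps[w]:
            if by_id[pid].status(w) != INCLUDED:
                raise InconsistencyError(
                    f"patient {pid} has a pattern label at {w} but status "
                    f"{by_id[pid].status(w)!r}"
                )

    flows: dict[tuple[str, str, str, str], int] = {}
    for wa, wb in zip(waves[:-1], waves[1:]):
        for pid, la in label_maps[wa].items():
            if pid in label_maps[wb]:
                target = pattern_node(label_maps[wb][pid])
            else:
                target = _absorbing_target(by_id[pid], wa, wb)
            key = (wa, pattern_node(la), wb, target)
            flows[key] = flows.get(key, 0) + 1
    return TrajectoryTable.from_flows(flows)


def trajectory_shares(
    table: TrajectoryTable,
    wave_from: str,
    node_from: str,
    wave_to: str,
    node_to: str,
    denominator: str = "source",
) -> float:
    """Percentage a flow represents of its source ("went to") or of its
    target ("came from")."""
    c = table.count(wave_from, node_from, wave_to, node_to)
    if denominator == "source":
        denom = table.outflow(wave_from, node_from)
    elif denominator == "target":
        denom = table.node_size(wave_to, node_to)
    else:
        raise ValueError("denominator must be 'source' or 'target'")
    if denom == 0:
        raise InconsistencyError(
            f"zero denominator for share {node_from}@{wave_from} -> "
            f"{node_to}@{wave_to}"
        )
    return 100.0 * c / denom


# ---------------------------------------------------------------------------
# Export: flows.csv and an alluvial figure
# ---------------------------------------------------------------------------

_FLOW_COLS = ["wave_from", "node_from", "wave_to", "node_to", "count"]


def write_flows(table: TrajectoryTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FLOW_COLS)
        for (wf, nf, wt, nt), c in sorted(table.flows.items()):
            writer.writerow([wf, nf, wt, nt, c])
    return path


def read_flows(path: str | Path) -> TrajectoryTable:
    flows: dict[tuple[str, str, str, str], int] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _FLOW_COLS:
            raise InconsistencyError(
                f"{path}: expected columns {_FLOW_COLS}, got {reader.fieldnames}"
            )
        for row in reader:
            key = (row["wave_from"], row["node_from"], row["wave_to"], row["node_to"])
            flows[key] = flows.get(key, 0) + int(row["count"])
    return TrajectoryTable.from_flows(flows)


def alluvial_layout(
    table: TrajectoryTable, gap: float = 0.02
) -> dict[str, dict[str, tuple[float, float]]]:
    """Vertical extents (y0, y1) per node and wave, on a 0..1 axis.

    Node heights are proportional to node sizes within each wave; `gap` is
    the fraction of the axis spent between boxes.
    """
    layout: dict[str, dict[str, tuple[float, float]]] = {}
    for w in table.waves:
        sizes = {nd: table.node_size(w, nd) for nd in table.nodes[w]}
        total = sum(sizes.values())
        n_gaps = max(len(sizes) - 1, 0)
        scale = (1.0 - gap * n_gaps) / total if total else 0.0
        y = 0.0
        layout[w] = {}
        for nd in table.nodes[w]:
            h = sizes[nd] * scale
            layout[w][nd] = (y, y + h)
            y += h + gap
    return layout


def draw_alluvial(table: TrajectoryTable, ax=None, gap: float = 0.02):
    """Render the flow table as an alluvial diagram.

    Boxes (nodes) and stripes (flows) have heights proportional to patient
    counts.  Returns (figure, layout).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    layout = alluvial_layout(table, gap=gap)
    if ax is None:
        fig, ax = plt.subplots(figsize=(2.5 * len(table.waves), 6))
    else:
        fig = ax.figure
    xpos = {w: i for i, w in enumerate(table.waves)}
    width = 0.12
    cmap = plt.get_cmap("tab10")
    colors = {}
    for w in table.waves:
        for idx, nd in enumerate(table.nodes[w]):
            if nd == DEATH_NODE:
                colors[(w, nd)] = (0.25, 0.25, 0.25, 1.0)
            elif nd == LOST_NODE:
                colors[(w, nd)] = (0.6, 0.6, 0.6, 1.0)
            else:
                colors[(w, nd)] = cmap(idx % 10)
            y0, y1 = layout[w][nd]
            ax.add_patch(
                Rectangle(
                    (xpos[w] - width / 2, y0), width, y1 - y0,
                    facecolor=colors[(w, nd)], edgecolor="black", linewidth=0.5,
                )
            )
            ax.text(
                xpos[w], (y0 + y1) / 2, f"{nd}\n{table.node_size(w, nd):,}",
                ha="center", va="center", fontsize=7,
            )
    # stripes: stack per source and per target in node order
    src_cursor = {(w, nd): layout[w][nd][0] for w in table.waves for nd in table.nodes[w]}
    tgt_cursor = dict(src_cursor)
    for wa, wb in zip(table.waves[:-1], table.waves[1:]):
        scale_a = {
            nd: (layout[wa][nd][1] - layout[wa][nd][0]) / table.node_size(wa, nd)
            for nd in table.nodes[wa] if table.node_size(wa, nd)
        }
        scale_b = {
            nd: (layout[wb][nd][1] - layout[wb][nd][0]) / table.node_size(wb, nd)
            for nd in table.nodes[wb] if table.node_size(wb, nd)
        }
        for nf in table.nodes[wa]:
            for nt in table.nodes[wb]:
                c = table.count(wa, nf, wb, nt)
                if not c:
                    continue
                ha = c * scale_a[nf]
                hb = c * scale_b[nt]
                ya = src_cursor[(wa, nf)]
                yb = tgt_cursor[(wb, nt)]
                src_cursor[(wa, nf)] = ya + ha
                tgt_cursor[(wb, nt)] = yb + hb
                xs = np.linspace(xpos[wa] + width / 2, xpos[wb] - width / 2, 50)
                t = (xs - xs[0]) / (xs[-1] - xs[0])
                ease = t * t * (3 - 2 * t)          # smoothstep ribbon
                lower = ya + (yb - ya) * ease
                upper = (ya + ha) + ((yb + hb) - (ya + ha)) * ease
                ax.fill_between(
                    xs, lower, upper, color=colors[(wa, nf)], alpha=0.35, lw=0
                )
    ax.set_xticks([xpos[w] for w in table.waves])
    ax.set_xticklabels(table.waves)
    ax.set_xlim(-0.5, len(table.waves) - 0.5)
    ax.set_ylim(-0.02, 1.02)
    ax.set_yticks([])
    for spine in ax.spines.values():
        spine.set_visible(False)
    return fig, layout


def export_alluvial(table: TrajectoryTable, outdir: str | Path) -> dict[str, Path]:
    """Write flows.csv and, when the table is non-empty, alluvial.svg."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"flows": write_flows(table, outdir / "flows.csv")}
    if table.flows:
        fig, _ = draw_alluvial(table)
        img = outdir / "alluvial.svg"
        fig.savefig(img)
        import matplotlib.pyplot as plt

        plt.close(fig)
        paths["plot"] = img
    return paths
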