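"""Classify module transitions between two conditions and overlay omic layers.

Rule table (defaults tau_major=0.5, tau_minor=0.2; f = |source ∩ target| /
|source|, measured on hard member sets):

==================================================  =============
condition on the source module's overlaps f         event
==================================================  =============
exactly one target with f > tau_major               persist
  ... and its rank band changed                     reposition
two or more targets with f >= tau_minor             split
  (none strictly above tau_major, or several)
exactly one target in [tau_minor, tau_major]        dissolve
all targets below tau_minor                         dissolve
==================================================  =============

Target-side events use the mirrored overlap g = |source ∩ target| / |target|:
``form`` when every source contributes g < tau_minor, ``merge`` when the
mirrored split rule fires. By construction the split events of
``map_modules(A, B)`` equal the merge events of ``map_modules(B, A)`` with
roles swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from omicnet.modules import ModuleSet

EVENT_KINDS = ("persist", "reposition", "split", "merge", "dissolve", "form")

DEFAULT_TAU_MAJOR = 0.5
DEFAULT_TAU_MINOR = 0.2
DEFAULT_MEMBER_THRESHOLD = 0.1
DEFAULT_RANK_BAND = 10


@dataclass
class ModuleEvent:
    kind: str
    sources: tuple[str, ...]
    targets: tuple[str, ...]
    overlaps: dict[str, float] = field(default_factory=dict)
    rank_change: tuple[int | None, int | None] | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "split" and (len(self.sources) != 1 or len(self.targets) < 2):
            raise ValueError("split needs one source and >=2 targets")
        if self.kind == "merge" and (len(self.sources) < 2 or len(self.targets) != 1):
            raise ValueError("merge needs >=2 sources and one target")
        if self.kind == "dissolve" and self.targets:
            raise ValueError("dissolve has no target")
        if self.kind == "form" and self.sources:
            raise ValueError("form has no source")


@dataclass
class LayerOverlay:
    node: str
    states: dict[str, str]  # layer -> up | down | unchanged | absent


def _band(rank: int | None, band_size: int) -> str | None:
    if rank is None:
        return None
    return "top" if rank <= band_size else "tail"


def _classify_sources(
    members_a: dict[str, set[str]],
    members_b: dict[str, set[str]],
    ranks_a: dict[str, int],
    ranks_b: dict[str, int],
    tau_major: float,
    tau_minor: float,
    band_size: int,
) -> list[ModuleEvent]:
    events = []
    for s in sorted(members_a):
        src = members_a[s]
        if not src:
            events.append(ModuleEvent("dissolve", (s,), (), {}))
            continue
        f = {t: len(src & members_b[t]) / len(src) for t in sorted(members_b)}
        major = [t for t, v in f.items() if v > tau_major]
        minor = [t for t, v in f.items() if v >= tau_minor]
        keep = {t: v for t, v in f.items() if v >= tau_minor}
        if len(major) == 1 and len(minor) == 1:
            t = major[0]
            kind = (
                "persist"
                if _band(ranks_a.get(s), band_size) == _band(ranks_b.get(t), band_size)
                else "reposition"
            )
            events.append(
                ModuleEvent(
                    kind, (s,), (t,), keep,
                    rank_change=(ranks_a.get(s), ranks_b.get(t)),
                )
            )
        elif len(major) == 1 and len(minor) > 1:
            # one dominant continuation with minor shed parts: still a
            # continuation of the major target
            t = major[0]
            kind = (
                "persist"
                if _band(ranks_a.get(s), band_size) == _band(ranks_b.get(t), band_size)
                else "reposition"
            )
            events.append(
                ModuleEvent(
                    kind, (s,), (t,), keep,
                    rank_change=(ranks_a.get(s), ranks_b.get(t)),
                )
            )
        elif len(minor) >= 2:
            events.append(ModuleEvent("split", (s,), tuple(sorted(keep)), keep))
        else:
            events.append(ModuleEvent("dissolve", (s,), (), keep))
    return events


def map_modules(
    ms_a: ModuleSet,
    ms_b: ModuleSet,
    tau_major: float = DEFAULT_TAU_MAJOR,
    tau_minor: float = DEFAULT_TAU_MINOR,
    member_threshold: float = DEFAULT_MEMBER_THRESHOLD,
    band_size: int = DEFAULT_RANK_BAND,
) -> list[ModuleEvent]:
    """Classify how the modules of ``ms_a`` evolve into those of ``ms_b``."""
    if not 0 < tau_minor <= tau_major <= 1:
        raise ValueError("need 0 < tau_minor <= tau_major <= 1")
    members_a = ms_a.hard_members(member_threshold)
    members_b = ms_b.hard_members(member_threshold)
    ranks_a = {c: r + 1 for r, c in enumerate(ms_a.ranked())}
    ranks_b = {c: r + 1 for r, c in enumerate(ms_b.ranked())}

    events = _classify_sources(
        members_a, members_b, ranks_a, ranks_b, tau_major, tau_minor, band_size
    )

    # target-side: merges are the reverse split rule; forms get no real mass
    reverse = _classify_sources(
        members_b, members_a, ranks_b, ranks_a, tau_major, tau_minor, band_size
    )
    for ev in reverse:
        if ev.kind == "split":
            events.append(
                ModuleEvent(
                    "merge",
                    sources=ev.targets,
                    targets=ev.sources,
                    overlaps=ev.overlaps,
                )
            )
    for t in sorted(members_b):
        tgt = members_b[t]
        if not tgt:
            continue
        g = {s: len(members_a[s] & tgt) / len(tgt) for s in members_a}
        if all(v < tau_minor for v in g.values()):
            events.append(ModuleEvent("form", (), (t,), {}))
    return events


def overlay_omics(
    ms: ModuleSet,
    layers: dict[str, list],
    thresholds: dict[str, float | None],
    member_threshold: float = DEFAULT_MEMBER_THRESHOLD,
) -> list[LayerOverlay]:
    """Per-node tri-layer state vector over the module set's nodes.

    ``layers`` maps a layer tag to differential records (anything with
    ``symbol``, ``p_value``, ``direction``). A node absent from a layer table
    is ``absent``; present and passing the layer threshold (``None`` =
    presence suffices) it is ``up``/``down`` by direction; present otherwise
    it is ``unchanged``.
    """
    unknown = set(layers) - set(thresholds)
    if unknown:
        raise ValueError(f"unknown layer tag(s): {sorted(unknown)}")
    tables = {
        tag: {r.symbol: r for r in recs} for tag, recs in layers.items()
    }
    out = []
    for node in sorted(ms.membership.index):
        states = {}
        for tag in layers:
            rec = tables[tag].get(node)
            if rec is None:
                states[tag] = "absent"
                continue
            thr = thresholds[tag]
            passed = thr is None or (rec.p_value is not None and rec.p_value < thr)
            if not passed:
                states[tag] = "unchanged"
            else:
                states[tag] = "up" if rec.direction >= 0 else "down"
        out.append(LayerOverlay(node=node, states=states))
    return out


def module_overlay_summary(
    ms: ModuleSet,
    overlays: list[LayerOverlay],
    member_threshold: float = DEFAULT_MEMBER_THRESHOLD,
) -> dict[str, dict[str, dict[str, int]]]:
    """Per-module counts of each state per layer (counts sum to module size)."""
    by_node = {o.node: o for o in overlays}
    summary: dict[str, dict[str, dict[str, int]]] = {}
    for label, members in ms.hard_members(member_threshold).items():
        layer_counts: dict[str, dict[str, int]] = {}
        for node in members:
            for tag, state in by_node[node].states.items():
                layer_counts.setdefault(tag, {}).setdefault(state, 0)
                layer_counts[tag][state] += 1
        summary[label] = layer_counts
    return summary
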