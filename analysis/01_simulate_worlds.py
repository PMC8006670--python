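#!/usr/bin/env python
"""Generate the three synthetic worlds the analysis runs on.

1. The canonical consistent world: a 60-gene forest GRN whose expression is
   actually driven by the network (plus sigma = 0.3 noise) under a schedule
   of knockout / overexpression / double-knockout / stress conditions.
2. Its decoupled counterpart: identical design but zero regulatory weights,
   so expression ignores the network (negative control).
3. A contrast-rich world with 30 perturbed and 30 unperturbed contrasts for
   the perturbed-vs-unperturbed comparison.

All three are written as the plain-text formats the pipeline consumes.
"""

from pathlib import Path

from grnsign.simulate import consistent_world, contrast_rich_world, decouple, write_world

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "worlds"


def main() -> None:
    w = consistent_world(SEED)
    write_world(w, OUT / "consistent")
    print(f"consistent world: {len(w.network.nodes)} genes, {w.network.n_edges} edges, "
          f"{len(w.compendium.samples)} samples, {len(w.contrasts)} contrasts")

    dw = decouple(w, SEED + 1)
    write_world(dw, OUT / "decoupled")
    print("decoupled world: same design, zero regulatory weights")

    wr = contrast_rich_world(SEED)
    write_world(wr, OUT / "contrast_rich")
    n_pert = sum(c.perturbed for c in wr.contrasts)
    print(f"contrast-rich world: {n_pert} perturbed vs "
          f"{len(wr.contrasts) - n_pert} unperturbed contrasts")


if __name__ == "__main__":
    main()
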