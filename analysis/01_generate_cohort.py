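#!/usr/bin/env python
"""Generate the synthetic cohort: nerve cross-sections and stimulation traces.

Writes per-animal fascicle tables and the four stimulation sessions
(laryngeal, pulmonary, cardiac efferent pre-vagotomy, cardiac afferent
post-vagotomy) for each of the 10 in vivo animals under results/cohort/,
and reports the cohort's composition against the expected means
(~1.2 cardiac, ~10.2 laryngeal, ~10.4 pulmonary, ~1.4 cardiopulmonary,
~6 laryngopulmonary fascicles per nerve).
"""

from collections import Counter
from dataclasses import replace
from pathlib import Path

import numpy as np

from vagusmap import RunConfig, generate_cross_section, simulate_session
from vagusmap.io import write_fascicle_table, write_trace_csv
from vagusmap.synthetic import default_protocol, draw_afferent_polarity

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1


def main() -> None:
    cfg = RunConfig.from_dict({"seed": SEED})
    OUT.mkdir(parents=True, exist_ok=True)
    totals: Counter = Counter()
    for i in range(cfg.n_svns):
        nerve, truth = generate_cross_section(cfg.synthetic, i, technique="svns")
        write_fascicle_table(nerve, OUT / f"{nerve.animal_id}_fascicles.csv")
        totals.update(f.organ_label for f in nerve.fascicles)
        polarity = draw_afferent_polarity(cfg.seed, i)
        for target, state in (
            ("laryngeal", "intact"),
            ("pulmonary", "intact"),
            ("cardiac_efferent", "intact"),
            ("cardiac_afferent", "right_distal"),
        ):
            model = replace(
                cfg.activation, vagotomy_state=state, afferent_polarity=polarity
            )
            traces = simulate_session(
                nerve, cfg.cuff, default_protocol(target, cfg.cuff.n_pairs),
                model, seed=cfg.seed * 1000 + i,
            )
            for t in traces:
                write_trace_csv(t, OUT / f"{nerve.animal_id}_{target}_{t.modality}.csv")
    n = cfg.n_svns
    print(f"Wrote {n} animals to {OUT}")
    print("Mean fascicle counts per nerve:")
    for organ, count in sorted(totals.items()):
        print(f"  {organ:18s} {count / n:.1f}")
    print(f"  total              {sum(totals.values()) / n:.1f}")


if __name__ == "__main__":
    main()
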