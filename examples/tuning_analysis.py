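"""Direction tuning of recorded channels before and after learning.

Runs a 12-session training series, then fits cosine tuning (rate on
target direction) to every channel in the first and last sessions.
Prints, for direct units, the change in tuning R^2 and in the
normalized |PD - AD| statistic (0 = preferred direction equals the
assigned direction, 1 = opposite).
"""

import numpy as np

import groupweight as gw
from groupweight import analysis

units = gw.make_population(rng=np.random.default_rng(7))
logs, _ = gw.run_training(
    units,
    gw.LearningSchedule(),
    n_sessions=12,
    decoder_cfg=gw.DecoderConfig(),
    task_cfg=gw.TaskConfig(),
    rng=np.random.default_rng(8),
    session_duration=180.0,
    pre_experiment_duration=60.0,
)


def direct_stats(log):
    tab = analysis.unit_tuning_table(log)
    r2s, dists = [], []
    for lab, group in zip(gw.GROUP_LABELS, log.group_spec.groups):
        ad = gw.sector_center(lab)
        for ch in group:
            row = tab.iloc[ch]
            r2s.append(row.r2)
            dists.append(gw.pd_ad_distance(row.pd_angle, ad))
    return np.mean(r2s), np.median(dists)


r2_first, d_first = direct_stats(logs[0])
r2_last, d_last = direct_stats(logs[-1])
print("direct units, session 1 : mean tuning R2 = %.3f, median |PD-AD| = %.2f" % (r2_first, d_first))
print("direct units, session 12: mean tuning R2 = %.3f, median |PD-AD| = %.2f" % (r2_last, d_last))

pn_first = analysis.session_potent_null(logs[0])
pn_last = analysis.session_potent_null(logs[-1])
print("mean output-potent value: %.2f (session 1) -> %.2f (session 12)"
      % (pn_first["mean_potent"].mean(), pn_last["mean_potent"].mean()))
print(
    "\nLearning sharpens tuning (higher R2), pulls preferred directions\n"
    "toward assigned directions (lower |PD-AD|), and raises the\n"
    "output-potent component — the part of group activity that actually\n"
    "moves the cursor."
)
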