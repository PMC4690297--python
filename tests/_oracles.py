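"""Independent brute-force oracle: full path enumeration of the decision tree.

Deliberately written as explicit loops over every tree path (group x shopper
type x picked cooler x picked shelf x purchase gate), independent of the
package's closed-form implementation.
"""

from coolernudge import ModelParams, PlacementLocation


def enumerate_tree_probability(loc: PlacementLocation, params: ModelParams) -> float:
    """Sum of path probabilities ending in a purchase of the item at ``loc``."""
    n_c = len(params.effects.horizontal)
    n_s = len(params.effects.vertical)
    weight = 1.0 / len(params.groups)
    total = 0.0
    for group in params.groups:
        lo, hi = group.base_range
        p_buy_given_seen = (lo + hi) / 2.0 / 100.0
        p_convenience = min(1.0, params.conv_baseline * group.loyalty)
        for shopper, p_type in (("convenience", p_convenience),
                                ("browser", 1.0 - p_convenience)):
            for cooler in range(1, n_c + 1):
                for shelf in range(1, n_s + 1):
                    v = params.effects.vertical[shelf - 1] / 100.0
                    if shopper == "convenience":
                        p_pick = v if cooler == 1 else 0.0
                    else:
                        p_pick = (params.effects.horizontal[cooler - 1] / 100.0) * v
                    if cooler == loc.cooler and shelf == loc.shelf:
                        total += weight * p_type * p_pick * p_buy_given_seen
    return total
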