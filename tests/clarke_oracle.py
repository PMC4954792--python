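"""Independently written brute-force Clarke zone classifier (test oracle).

Re-derived from the published grid geometry region by region, structured as
exhaustive region membership checks rather than the short-circuit cascade
used by the implementation. Kept deliberately separate so the two code
paths share nothing.
"""


def clarke_zone_oracle(ref: float, pred: float) -> str:
    in_a = (pred >= 0.8 * ref and pred <= 1.2 * ref) or (ref <= 70 and pred <= 70)

    upper_e = ref <= 70 and pred >= 180          # hypo read as hyper
    lower_e = ref >= 180 and pred <= 70          # hyper read as hypo
    in_e = upper_e or lower_e

    upper_c = 70 <= ref <= 290 and pred >= ref + 110
    lower_c = 130 <= ref <= 180 and pred <= 1.4 * ref - 182
    in_c = upper_c or lower_c

    band = 70 <= pred <= 180
    upper_d = ref <= 175.0 / 3.0 and band
    mid_d = 175.0 / 3.0 <= ref <= 70 and pred >= 1.2 * ref
    lower_d = ref >= 240 and band
    in_d = upper_d or mid_d or lower_d

    for zone, hit in (("A", in_a), ("E", in_e), ("C", in_c), ("D", in_d)):
        if hit:
            return zone
    return "B"
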