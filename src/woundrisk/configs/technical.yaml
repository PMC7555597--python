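# Default Technical Risk engine.
#
# Inputs: the Braden-scale total (6-23, lower = higher pressure-ulcer risk)
# and the wound-area change rate normalized to percent of the reference area
# per day (negative = healing).  Output: Technical Risk on [10, 100].
#
# The rule table is full-factorial 3x3, monotone in both risk-increasing
# directions and "smooth" (adjacent cells differ by at most one output
# level), which together with symmetric output sets keeps the defuzzified
# output monotone everywhere.  The partition is calibrated on the canonical
# worked case shipped with the package (Braden total 14, wound shrinking at
# 1% of its reference area per day), which lands fully on the 'low' output
# set and yields a Technical Risk of 40.
inputs:
  - name: braden_total
    domain: [6, 23]
    sets:
      - {label: severe, points: [6, 6, 9, 12]}
      - {label: moderate, points: [9, 12, 16, 19]}
      - {label: mild, points: [16, 19, 23, 23]}
  - name: area_rate_pct
    domain: [-5, 5]
    sets:
      - {label: shrinking, points: [-5, -5, -1, -0.2]}
      - {label: stable, points: [-1, -0.2, 0.2, 1]}
      - {label: growing, points: [0.2, 1, 5, 5]}
output:
  # symmetric trapezoids (equal edge widths), so each set's centroid is
  # invariant under truncation; centroids 15 / 40 / 57.5 / 75 / 90
  name: technical_risk
  domain: [10, 100]
  sets:
    - {label: very_low, points: [10, 13, 17, 20]}
    - {label: low, points: [35, 38, 42, 45]}
    - {label: medium, points: [52.5, 55.5, 59.5, 62.5]}
    - {label: high, points: [70, 73, 77, 80]}
    - {label: very_high, points: [85, 88, 92, 95]}
rules:
  - {if: {braden_total: mild, area_rate_pct: shrinking}, op: and, then: very_low}
  - {if: {braden_total: mild, area_rate_pct: stable}, op: and, then: low}
  - {if: {braden_total: mild, area_rate_pct: growing}, op: and, then: medium}
  - {if: {braden_total: moderate, area_rate_pct: shrinking}, op: and, then: low}
  - {if: {braden_total: moderate, area_rate_pct: stable}, op: and, then: medium}
  - {if: {braden_total: moderate, area_rate_pct: growing}, op: and, then: high}
  - {if: {braden_total: severe, area_rate_pct: shrinking}, op: and, then: medium}
  - {if: {braden_total: severe, area_rate_pct: stable}, op: and, then: high}
  - {if: {braden_total: severe, area_rate_pct: growing}, op: and, then: very_high}
defuzz_grid: 1001
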