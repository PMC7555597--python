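# Default Expert Risk engine.
#
# Inputs: three qualitative ratings on 0-10 scales supplied by the wound
# expert — evaluation of the images, the patient's health history, and other
# risk factors.  Output: Expert Risk on [10, 100].
#
# The rule table is full-factorial 3x3x3, derived from a weighted severity
# score (health history weighted twice as heavily as the other two ratings),
# monotone in every input and "smooth" (changing one input by one level
# moves the consequent by at most one level), which together with symmetric
# output sets keeps the defuzzified output monotone everywhere.  The
# partition is calibrated on the canonical worked case shipped with the
# package (ratings 3/8/4), which lands on the 'high' output set and yields
# an Expert Risk of 70.
inputs:
  - name: image_evaluation
    domain: [0, 10]
    sets:
      - {label: low, points: [0, 0, 2, 4]}
      - {label: medium, points: [2, 4, 6, 8]}
      - {label: high, points: [6, 8, 10, 10]}
  - name: health_history
    domain: [0, 10]
    sets:
      - {label: low, points: [0, 0, 2, 4]}
      - {label: medium, points: [2, 4, 6, 8]}
      - {label: high, points: [6, 8, 10, 10]}
  - name: other_risk_factors
    domain: [0, 10]
    sets:
      - {label: low, points: [0, 0, 2, 4]}
      - {label: medium, points: [2, 4, 6, 8]}
      - {label: high, points: [6, 8, 10, 10]}
output:
  # symmetric trapezoids with centroids 15 / 35 / 52.5 / 70 / 90
  name: expert_risk
  domain: [10, 100]
  sets:
    - {label: very_low, points: [10, 13, 17, 20]}
    - {label: low, points: [30, 33, 37, 40]}
    - {label: medium, points: [47.5, 50.5, 54.5, 57.5]}
    - {label: high, points: [65, 68, 72, 75]}
    - {label: very_high, points: [85, 88, 92, 95]}
rules:
  - {if: {image_evaluation: low, health_history: low, other_risk_factors: low}, op: and, then: very_low}
  - {if: {image_evaluation: low, health_history: low, other_risk_factors: medium}, op: and, then: low}
  - {if: {image_evaluation: low, health_history: low, other_risk_factors: high}, op: and, then: low}
  - {if: {image_evaluation: low, health_history: medium, other_risk_factors: low}, op: and, then: low}
  - {if: {image_evaluation: low, health_history: medium, other_risk_factors: medium}, op: and, then: medium}
  - {if: {image_evaluation: low, health_history: medium, other_risk_factors: high}, op: and, then: medium}
  - {if: {image_evaluation: low, health_history: high, other_risk_factors: low}, op: and, then: medium}
  - {if: {image_evaluation: low, health_history: high, other_risk_factors: medium}, op: and, then: high}
  - {if: {image_evaluation: low, health_history: high, other_risk_factors: high}, op: and, then: high}
  - {if: {image_evaluation: medium, health_history: low, other_risk_factors: low}, op: and, then: low}
  - {if: {image_evaluation: medium, health_history: low, other_risk_factors: medium}, op: and, then: low}
  - {if: {image_evaluation: medium, health_history: low, other_risk_factors: high}, op: and, then: medium}
  - {if: {image_evaluation: medium, health_history: medium, other_risk_factors: low}, op: and, then: medium}
  - {if: {image_evaluation: medium, health_history: medium, other_risk_factors: medium}, op: and, then: medium}
  - {if: {image_evaluation: medium, health_history: medium, other_risk_factors: high}, op: and, then: high}
  - {if: {image_evaluation: medium, health_history: high, other_risk_factors: low}, op: and, then: high}
  - {if: {image_evaluation: medium, health_history: high, other_risk_factors: medium}, op: and, then: high}
  - {if: {image_evaluation: medium, health_history: high, other_risk_factors: high}, op: and, then: very_high}
  - {if: {image_evaluation: high, health_history: low, other_risk_factors: low}, op: and, then: low}
  - {if: {image_evaluation: high, health_history: low, other_risk_factors: medium}, op: and, then: medium}
  - {if: {image_evaluation: high, health_history: low, other_risk_factors: high}, op: and, then: medium}
  - {if: {image_evaluation: high, health_history: medium, other_risk_factors: low}, op: and, then: medium}
  - {if: {image_evaluation: high, health_history: medium, other_risk_factors: medium}, op: and, then: high}
  - {if: {image_evaluation: high, health_history: medium, other_risk_factors: high}, op: and, then: high}
  - {if: {image_evaluation: high, health_history: high, other_risk_factors: low}, op: and, then: high}
  - {if: {image_evaluation: high, health_history: high, other_risk_factors: medium}, op: and, then: very_high}
  - {if: {image_evaluation: high, health_history: high, other_risk_factors: high}, op: and, then: very_high}
defuzz_grid: 1001
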