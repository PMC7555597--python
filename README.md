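# woundrisk

Decision support for monitoring pressure-ulcer (PU) treatment. Given a pair
of dated wound photographs, a Braden-scale assessment and three qualitative
ratings from a wound expert, `woundrisk` quantifies the wound area, runs two
concurrent Mamdani fuzzy inference engines, fuses their outputs into a
single Global Risk score, and maps that score onto one of three clinical
recommendations: *continue* the current treatment, *evaluate alternative*
treatments, or *change treatment immediately*.

It is written for clinical-informatics researchers and engineers who want a
tested, scriptable implementation of this risk-fusion methodology rather
than a GUI.

## The model

Two crisp risk scores on [10, 100] are produced by Mamdani engines
(trapezoidal membership functions, min/max rule evaluation, min
implication, max aggregation, centroid defuzzification):

* **Technical Risk (RT)** — from the Braden total (6–23, lower = higher
  risk) and the wound-area change rate ΔArea/ΔTime, normalized to percent
  of the reference area per day. The area itself comes from seeded
  region-growing segmentation of the inverted HSV saturation plane,
  calibrated against a reference marker of known physical size in the frame.
* **Expert Risk (RE)** — from the expert's 0–10 ratings of the images, the
  patient's health history, and other risk factors.

They are fused through a **Decision Factor** f(RT, RE) and the
**Global Risk**

```
RG(RT, RE) = RT · f(RT, RE) / 10          (clamped at 100)

f(RT, RE) = f1(RT)^(RE − f2(RT)) + 10     for RT ≤ 50   (exponential zone)
f(RT, RE) = f3(RT)·ln(RE) + f4(RT)        for RT > 50   (logarithmic zone)

f1(RT) = −0.0015·RT + 1.1391       f3(RT) = 215.3·RT^−1.005
f2(RT) = −0.0085·RT² + 0.5092·RT + 57.247   f4(RT) = −0.0048·RT + 0.7849
```

Below the zone boundary the expert's judgment can raise the risk sharply
(exponential growth in RE); above it the technical evidence dominates and
high RG is reachable even at low RE. The expert may reshape the surface with
a chord-interpolation correction on an RE interval (exponential zone), a
certainty rescaling by 100/security when RG falls more than 20 % below RT
(logarithmic zone), and a second-level sigmoidal blend of RG across the
zone boundary on an RT interval inside [25, 75].

RG is banded into the three alerts with half-open intervals
[0–60), [60–80), [80–100], all reconfigurable.

## Worked example

The documented clinical case — a patient with Braden total 14 whose wound
shrank from 10 cm² to 7 cm² over 30 days (−1 % of the reference area per
day), rated 3/10, 8/10 and 4/10 by the expert:

```sh
$ woundrisk assess --braden 2,3,1,2,4,2 --rate-pct -1.0 --expert 3,8,4
{"technical_risk": 40.0, "expert_risk": 70.0}

$ woundrisk fuse --rt 40 --re 70
{"df": 11.58, "df_corrected": 11.58, "rg": 46.31, "rg_corrected": 46.31,
 "alert": "continue", "corrections_applied": []}
```

RT = 40 and RE = 70 give a Decision Factor of 11.58 and a Global Risk of
46.31, which falls in the [0–60) band: the recommendation is to continue
the current treatment.

The same pipeline runs end-to-end from images
(`woundrisk segment`, `woundrisk report --case case.yaml`), and
`woundrisk fixtures --out dir/` generates synthetic wound-photo pairs with
known ground-truth areas for testing. Everything the CLI does is available
as library functions (`woundrisk.fuse`, `woundrisk.run_case`,
`woundrisk.measure_wound`, ...).

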