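# Methods

This note records the models, conventions, and numerical choices behind
`adpkd_metrics`, in the spirit of a model-documentation page: what each
metric assumes, which knobs matter, and what the synthetic phantoms do and
do not demonstrate.

## Grids, volumes, units

All measurements live on a 3D voxel lattice with physical spacing in mm
per axis. Voxel indices are 0-based; the world coordinate of voxel
(i, j, k) is `origin + (i, j, k) · spacing`, and the origin is the center
of voxel (0, 0, 0). Orientation is a per-axis anatomical direction label
(RAS by default), used only to name bounding-box extents (craniocaudal,
left–right, anteroposterior). Organ volume is exact integer voxel
counting times the voxel volume (product of spacings), converted to mL
(1 mL = 1000 mm³). Volumes are carried at full precision everywhere;
rounding to the nearest mL is purely presentational and happens only when
the report is rendered.

## Acquisition normalization

Multi-breath-hold "upper"/"lower" stacks are merged by taking the union
of slice positions; a duplicated position keeps the first (upper) series'
slice — overlap is discarded, not averaged, which keeps the merge
deterministic and idempotent (averaging remains an open alternative; the
replacement rule is the implemented default). When in-plane resolutions
differ, both stacks are resliced to the finer spacing — linear
interpolation for intensities, nearest-neighbor for label maps, so labels
stay integer-coded. Stacks separated by more than one slice thickness are
rejected as a coverage gap; a single missing slice position is filled by
averaging its two neighbors. Multi-echo and multi-b-value containers are
split into one series per tag; splitting is a partition (counts
conserved, outputs disjoint). For two-point Dixon containers the first
echo is classed out-of-phase and the second in-phase, following the echo
ordering at 1.5 T. A series' representative time is the mean of its
per-image timestamps: each image's DICOM timestamp is instantaneous, but
dynamic metrics (bladder filling) are resolved per series.

## Multi-sequence aggregation and QC

Each organ is measured on every geometrically reliable sequence of an
exam; localizer, calibration, DWI, and ADC maps never enter volumetry
(low resolution, gradient-warp distortion). The summary is the mean and
sample SD (ddof = 1; a single series reports SD 0 with n = 1). Outlier
flagging uses a median rule: with n ≥ 3 eligible series, a series is
flagged when its volume deviates from the median by more than 10 % of the
median. The threshold is configurable; the rule is deliberately robust
(one bad series cannot drag the reference point far) and is a reviewing
trigger, not an automatic exclusion. The reported organ volume defaults
to the cross-sequence mean; a designated reference sequence can be chosen
instead. The 500 mL saline-bag check passes when the relative volume
error is within 5 % (configurable).

## Renal metrics

TKV is the sum of both kidney volumes; htTKV divides by height in metres.
Growth is modelled as exponential enlargement: OLS of ln TKV on age,
annualized rate `r = exp(slope) − 1`. The fit requires ≥ 2 exams spanning
≥ 1 year (closer exams carry too little growth relative to measurement
noise); with exactly two points it reduces to the closed form
`ln(V₂/V₁)/(a₂ − a₁)` with r² = 1. Rapid progression is strictly
`r > 5 %/yr`. Whether to regress on age or on exam-date offset is
equivalent up to the intercept; age is used so the growth model and the
Mayo classification share an axis.

The Mayo Imaging Classification (class 1 subclasses only) back-solves the
same exponential model from a single exam, anchored at a theoretical
htTKV of 150 mL/m at age 0: `r̂ = (htTKV/150)^(1/age) − 1`, classed 1A–1E
at boundaries 1.5/3/4.5/6 %/yr (half-open, boundary value into the upper
class). The constants live in a config dataclass. htTKV below 150 mL/m
gives a non-positive rate, class 1A, with an explicit below-baseline
note. Atypical (class 2) morphology is out of scope: the classifier
assumes typical diffuse bilateral disease. Pre- vs post-treatment
trajectories are two independent fits on a user-supplied partition age —
the partition is clinical input (treatment start), never inferred.

## Liver fat fraction

Two-point Dixon: per voxel `FF = (S_IP − S_OP) / (2 · S_IP)`. The mask is
the liver segmentation minus hepatic cysts and IVC, eroded at the
boundary so partial-volume peripheral fat does not contaminate the
estimate. Erosion and dilation are physical: Euclidean distance
transforms with the anisotropic spacings, thresholded in mm (default
erosion 3 mm ≈ two voxel layers at typical in-plane resolution). Two
summaries are reported: the masked mean (clamped to [0, 1]) and the
histogram peak. The histogram uses a fixed 0.01 bin width over [−0.5, 1]
with bin *centers* on the 0.01 grid (edges at k·0.01 ± 0.005), so exact
grid values such as 0.18 fall inside the bin centered on them rather
than on an edge; ties take the lower-FF bin. The peak estimator is robust
to residual cyst/vessel voxels, which inflate the mean. Raw negative FF
values stay in the histogram but are clamped in summaries; when more than
1 % of mask voxels are negative a swap flag signals a probable partial
fat–water swap. The two-point method cannot distinguish fat-dominant
voxels (FF and 1 − FF give the same signal magnitude), so the phantom
refuses FF ≥ 0.5 and the estimator makes no claim beyond flagging.

## Body composition

Cyst-corrected weight subtracts the renal + hepatic cyst burden at a
density of 1 g/mL (water-like cyst fluid): litres of cyst convert 1:1 to
kilograms. Both BMIs are weight/height²; the corrected one uses the
corrected weight, and by construction never exceeds the uncorrected
value. Compartment volumes (visceral/subcutaneous fat, muscle) are
whole-volume by default, with an optional inclusive axial slice band for
single-level indices (e.g. L3 sarcopenia metrics) — the single-level
convention varies across studies, so both are exposed.

## Urine output and ureteral jets

Bladder volume is measured per series; the OLS slope of volume against
the series' representative acquisition time, converted to mL/hour and
divided by weight, is the urine output in mL/kg/h (clinical typical range
0.5–1.5). T1-class series are excluded from the fit by default (they
systematically under-segment the bladder) but are retained in the
exported point table with their exclusion reason. The fit is invariant
to a constant shift of all timestamps.

The jet screen is explicitly heuristic: flow voids from urine jets raise
the within-bladder intensity SD, so the flag fires when SD/median exceeds
0.05 (configurable), and voxels below median − 2·SD are counted as
candidate voids. It is reported as a flag with evidence counts only.

## Gastric confinement

Postprandial distension is simulated by dilating the stomach mask by
10 mm of Euclidean distance (physical mm, anisotropic-aware; default
configurable). The shell (dilated minus stomach) is partitioned: each
shell voxel belongs to the neighbor organ whose label occupies it, else
to "free". Label maps are single-coded, so the partition is exact and the
fractions sum to 1. Dilation is 3D by default with an axial-only
(per-slice 2D) mode, since a purely in-plane reading of the expansion is
also defensible. A shell reaching the grid boundary is reported as
truncated. Increasing the dilation never shrinks the shell.

## Phantoms: what they show and what they don't

Phantom organs are boxes and ellipsoids rasterized by the center-inside
rule, which makes voxel counts deterministic and lets ground truth be
recorded from the same voxel sets the measurements will count — measured
and true volumes agree exactly by construction, and rasterized ellipsoids
converge to the analytic volume as spacing shrinks. Dixon pairs encode a
chosen FF exactly (`S_OP = S_IP(1 − 2·FF)`); bladder series follow a
linear filling law with rasterization error under one voxel layer;
longitudinal TKV histories follow exact exponential growth with optional
lognormal measurement noise. Gaussian noise is applied to intensities
only, never to labels — segmentation is an input to this tool, so label
noise would test a different system. Consequently, passing phantom tests
demonstrates the correctness of the *measurement* pipeline, not
robustness to segmentation error, motion, coil shading, dielectric
artifact, or partial volume at real organ boundaries.

Default test problem sizes (grids of 30³–120³ voxels at 1–2 mm, growth
recovery at n = 6 exams × 200 replicates, FF recovery on ~50k-voxel
masks) were chosen as the smallest scales at which rasterization error is
negligible relative to the tolerances being checked.

## Degenerate inputs and tie-breaks

Empty masks: volume 0 and "absent", but bounding boxes and parenchymal
masks raise — a dimension of nothing is undefined. Single eligible
series: SD 0, n = 1, no outlier test. Exactly-threshold values: presence
uses ≥ min-volume (default 0.05 mL, below which a finding is reported but
flagged absent/small); rapid progression uses strict >; Mayo boundaries
are half-open upward. Histogram mode ties break toward lower FF. Merge
overlap keeps the first series. All randomness is seeded; fixed seed
means voxel-identical phantoms and byte-identical reports.

## Known limitations

- Two-point Dixon only; no multi-echo fat quantification or T2* correction.
- Mayo class 2 (atypical) is not classified.
- Cyst-by-cyst instance metrics (counts, per-cyst surface area) are out
  of scope; cysts are treated as pooled label volumes.
- The jet statistic is a screening heuristic without a validated
  threshold.
- DICOM support is metadata-only (time/echo/b tags); voxel data must
  arrive as NIfTI from a dedicated converter.
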