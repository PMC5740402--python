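# Methods

## Measurement model

A chromosome is represented by the polyline path a user would trace along
its axis on a metaphase photograph. All downstream quantities live in *arc
length* along that path: the chromosome length `L` is the sum of Euclidean
segment lengths; the centromere is a single arc position splitting `L` into
short arm `Ls` and long arm `Ll`; landmarks (point signals, bands,
satellites) are arc intervals `[arc_start, arc_end]`; GISH painting is a
list of colored arc intervals covering part or all of the body. Coordinates
are continuous pixels, origin top-left, y down.

**Fragment joining.** Chromosomes broken during spreading are traced as
several fragments; their arc-length spaces are concatenated in order and the
spatial gap between consecutive fragments contributes zero length, because
the bridging distance is an artifact of spreading, not chromatin.

**Orientation normalization.** Which telomere a user starts tracing from is
arbitrary, so after the centromere is placed the path is reflected
(`arc′ = L − arc`, applied to the centromere, landmarks and segments alike)
whenever the marked arc lies past the midpoint. Afterwards
`Ls = centromere_arc ≤ L/2 ≤ Ll` always holds, making CI ≤ 50 an invariant
rather than a convention the user must remember. The operation is
idempotent; an exact metacentric (arc = L/2) is left unflipped and arm
labels follow path order. A zero-width landmark exactly at the centromere
is assigned to the p arm; an interval touching the centromere at one end
belongs to the arm holding the rest of the interval.

**Calibration.** A traced scale bar of known physical length gives
`pixels_per_micron = bar_arc_length / known_um`. Without a calibration all
outputs are flagged `unit="px"`; the unit is always carried explicitly in
tables rather than implied.

## Karyotype statistics

- CI = 100·Ls/L; arm ratio r = Ll/Ls (long over short, the standard
  cytogenetic convention; r is "undefined", not an error, when Ls = 0).
- Relative length uses the **whole measured complement** as denominator, so
  ΣRL = 100 over a metaphase. Users comparing against haploid-set
  conventions can multiply by the ploidy.
- Chromosomes are ordered by decreasing length (ties: decreasing CI, then
  name) and numbered from 1 starting with the largest; measurement names
  can be preserved with a flag when name-based matching matters.
- Holocentric/unassigned centromeres propagate as absent arm statistics,
  never as zeros.

**Averaging.** Two distinct, deliberately different matching rules:
`reduce_karyotype` (monoploid reduction) groups strictly by length rank —
consecutive groups of `ploidy` after sorting — because homolog identity
within one metaphase is positional; `average_karyotypes` (multi-metaphase
averaging) matches strictly by chromosome name, because identity across
metaphases is the user's naming. Both report means and *sample* standard
deviations (n − 1); a group of one gets SD 0 and is flagged through `n`.
`mean_CI` is the mean of per-sample CIs; the renderer derives the drawn arm
split from `mean_L · mean_CI/100`, accepting the mild inconsistency with
`mean_Ls`/`mean_Ll`, which are still reported in tables. Length-rank
grouping can misgroup wildly unequal homologs; that risk is inherent to the
rule and left to the user's complement.

## Idiogram rendering

Layout produces a resolution-independent scene: one glyph per record, in
record order (the renderer never re-sorts), vertical bodies, short arm up,
glyph height strictly proportional to `L` (or `mean_L`) through one shared
scale factor (longest chromosome = 200 drawing units by default). Default
alignment puts every centromeric constriction on one shared horizontal
line, which makes arm-length differences directly comparable; top alignment
is available. Landmarks map affinely: a glyph position is
`top + frac · height`. Point signals draw as flank dots, bands and GISH
segments as full-width sub-rectangles, satellites with a thin white gap
marking the secondary constriction. For averaged karyotypes (and only
then), error bars show `±sd_L` at the long-arm telomere and `±sd_Ls` at the
constriction. The centromere is a symmetric bowtie overlay so body height
stays exactly proportional to length.

SVG output is hand-emitted XML with fixed number formatting (3 decimals,
trailing zeros stripped), one `<g class="chromosome">` per glyph — identical
scenes give byte-identical files. PNG is rasterized from the same primitive
list through matplotlib at a caller-chosen DPI, so the two back ends cannot
drift apart geometrically. The fixed default palette keeps repeated renders
reproducible.

## File formats

Measurements travel as a versioned JSON schema (validated by a small
purpose-built checker whose errors carry JSON-pointer paths). Writers are
canonical — sorted keys, stable float repr — so write∘read∘write is
byte-stable. Karyotype tables are xlsx workbooks with exactly two sheets,
`Chromosomes` and `Metadata`; SD/n columns appear only for averaged
karyotypes, and `Metadata` carries landmark rows plus `segment` and
`chromosome_color` rows so GISH painting and per-chromosome colors survive
the round trip. A CSV mirror (one file per sheet) is provided. The storage
container is an append-only JSON file of named karyotypes with unique-name
enforcement; averaging stored entries is exactly equivalent to averaging
the in-memory objects. Spreadsheet floats are serialized at ~16 significant
digits, so any JSON → xlsx → JSON loop agrees to far better than the 1e-9
relative contract; raster images are accepted only as opaque provenance
references, never parsed.

## Synthetic data generator

The generator emulates the *traced paths*, not the photograph: each
chromosome is a gently curving random walk rescaled to an exact arc length
(uniform scaling scales arc length linearly, so ground truth is exact to
float precision), centered in a non-overlapping grid cell at a random pose,
with a centromere, optional landmarks and a traced scale bar at
12 px/µm. Homolog-group nominal lengths and CIs are drawn uniformly
(defaults 4–14 µm, CI 25–50 %); each copy jitters both multiplicatively by
`1 + N(0, noise_sd)` (CI clipped to (5, 50]); path orientation is random so
the normalizer is exercised; fragments can be split to exercise joining. A
separate `base_seed` freezes the nominal karyotype while `seed` varies the
noise, emulating repeated metaphases of one individual. 5 % relative noise
across metaphases is used as the realistic between-plate variability in the
recovery studies (20 metaphases of 8–10 chromosome groups).

What the generator does **not** emulate: chromatin texture, bent/overlapping
chromosomes, condensation differences between plates, segmentation errors,
or operator digitization noise along the path. Passing recovery tests
therefore show that the *computational* pipeline is unbiased and lossless
given faithful traces — not that tracing real images is error-free.

Species presets reproduce published complement sizes and landmark topology
(hemp 2n = 20 with color-flagged sex and NOR pairs; *Rosa wichurana*
2n = 14 with red satellites on the two shortest chromosomes; *Allium cepa*
and *A. fistulosum* 2n = 16, the latter with 5S rDNA and HAT58 landmarks;
a ×*Festulolium* F2 recombinant with 2n = 34 and two-color genome painting
with breakpoints on four chromosomes). Their numeric lengths and CIs are
synthetic placeholders, not published measurements.

## Statistical checks and numerical choices

Zero-noise fixtures must round-trip the full JSON → stats → xlsx → idiogram
pipeline with ≤ 1e-6 relative error (observed: ~1e-15). For noisy
multi-metaphase recovery, each chromosome's recovered mean is compared to
its nominal value via the z-score against the analytic standard error
`L₀·σ/√n`. Because a study of ~10 chromosomes yields ~20 such z-scores, a
joint "every |z| < 3" assertion would fail about 5 % of the time for a
perfectly correct implementation; the tests therefore allow at most one
3-SE excursion among all z-scores and additionally require mean |z| < 1.5,
which keeps the false-alarm rate below 0.2 % while still detecting small
systematic biases. Sample SDs must fall within 50 % of nominal at n = 20.

Other numerical conventions: geometric invariance tolerances are 1e-9
relative; xlsx/JSON round-trip tolerance 1e-9 relative; idiogram affine
placement is checked to 0.5 drawing units; ties in length ordering break by
CI then name so ordering is total and deterministic; all randomness flows
from explicit integer seeds.

## Known limitations

- No image processing: chromosome paths must come from elsewhere (the JSON
  format is the integration point); `image_ref` is provenance only.
- Length-rank homolog grouping in monoploid reduction assumes a sensible
  complement (see above).
- Karyotype asymmetry indices (TF %, CV_CL, M_CA, …) are out of scope.
- xlsx files are data-deterministic but not byte-deterministic (zip
  container metadata); SVG is byte-deterministic.
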