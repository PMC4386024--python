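# File formats

All tables are plain CSV with a header row; trace matrices are HDF5 or
NPZ, chosen by extension.  Every codec in `preyscope.io` round-trips its
numeric fields.

## schedule.csv
One row per 32 s epoch.

| column | type | meaning |
|---|---|---|
| epoch_index | int | 0-based, onsets are `epoch_index * 32` s |
| stimulus_id | int | 0–15 moving spots (`8·dir + 4·speed + 2·size + pol`), 16 dim flash, 17 bright flash |
| direction, speed, size, polarity | int | feature bits; −1 for flashes |
| epoch_onset | float s | absolute onset |
| plane | int | focal plane index |

## eyes.csv
`t` (s), `left_deg`, `right_deg` — 60 Hz binocular horizontal eye
positions, nasal-positive per eye (vergence = left + right).

## events.csv
One row per convergent saccade: onset time, per-eye pre/post window means,
displacements, peak nasal velocities, `evoked` flag, `epoch_index` (−1 if
spontaneous), spot azimuth at onset (empty if spontaneous).

## rois.csv
`roi_id, fish_id, plane_z, x, y, hemisphere, region` — centroids in μm,
region one of `OTc-SPV-L/R`, `OTc-Np-L/R`, `Hb-L/R`, `TL`, `other`.

## traces.h5 / traces.npz
Datasets `traces` (frames × ROIs, ΔF/F on the 57-frames-per-epoch grid)
and `roi_ids` (column order).

## ground_truth.json
Generator provenance: per-ROI archetype/amplitude/RF, assembly membership
with lead frames and paired event, and the planted saccade list.

## Movies
Multi-page TIFF, one page per imaging frame, float32.
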