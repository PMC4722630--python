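# Packaged normal-size knowledge base.
#
# Bounds are inclusive.  Units are normalised to mm at load time.
# The spleen is described by three intervals (height along the
# craniocaudal axis, length and width at the hilum); the alternative
# single upper bound on spleen length is shipped disabled because the
# three-interval form is what the classifier's worked examples use.

- id: ln-short-axis
  entity_id: RID13296        # lymph node
  quality: short axis
  range_type: upper_bound
  high: 1
  unit: cm

- id: submental-ln-short-axis
  entity_id: RID7710         # submental lymph node
  quality: short axis
  range_type: upper_bound
  high: 1.5
  unit: cm

- id: spleen-height
  entity_id: RID86
  quality: height
  range_type: interval
  low: 11
  high: 15
  unit: cm

- id: spleen-length
  entity_id: RID86
  quality: length
  range_type: interval
  low: 7
  high: 10
  unit: cm

- id: spleen-width
  entity_id: RID86
  quality: width
  range_type: interval
  low: 4
  high: 6
  unit: cm

- id: spleen-length-upper-alt
  entity_id: RID86
  quality: length
  range_type: upper_bound
  high: 15
  unit: cm
  enabled: false             # alternative guideline; conflicts with spleen-length

- id: ascending-aorta-root-diameter
  entity_id: RID580          # ascending aorta, diameter at the root
  quality: diameter
  range_type: lower_bound
  low: 4
  unit: cm

- id: kidney-craniocaudal
  entity_id: RID205
  quality: craniocaudal diameter
  range_type: interval
  low: 8
  high: 13
  unit: cm

- id: gallbladder-wall-thickness
  entity_id: RID33779
  quality: thickness
  range_type: interval
  low: 0.1
  high: 0.3
  unit: cm

- id: ureter-width
  entity_id: RID229
  quality: width
  range_type: interval
  low: 0.4
  high: 0.7
  unit: cm
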