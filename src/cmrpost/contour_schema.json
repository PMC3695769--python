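{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "cmrpost contour exchange format",
 "type": "object",
 "required": ["slices", "contours"],
 "properties": {
  "slices": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["index", "z_mm", "thickness_mm"],
    "properties": {
     "index": {"type": "integer", "minimum": 0},
     "z_mm": {"type": "number"},
     "thickness_mm": {"type": "number", "exclusiveMinimum": 0},
     "gap_mm": {"type": "number", "minimum": 0},
     "pixel_spacing_mm": {
      "type": "array", "items": {"type": "number", "exclusiveMinimum": 0},
      "minItems": 2, "maxItems": 2
     }
    }
   }
  },
  "contours": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["slice", "phase", "role", "points_mm"],
    "properties": {
     "slice": {"type": "integer", "minimum": 0},
     "phase": {"type": "integer", "minimum": 0},
     "role": {
      "enum": ["endocardial", "epicardial", "papillary", "blood_pool_roi",
               "remote_roi", "skeletal_muscle_roi", "scar_core_roi",
               "vessel_lumen", "generic"]
     },
     "points_mm": {
      "type": "array", "minItems": 3,
      "items": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
     }
    }
   }
  },
  "meta": {
   "type": "object",
   "properties": {
    "heart_rate_bpm": {"type": ["number", "null"], "exclusiveMinimum": 0},
    "bsa_m2": {"type": ["number", "null"], "exclusiveMinimum": 0},
    "acquisition_plane": {"enum": ["short_axis", "transaxial", "long_axis"]}
   }
  }
 }
}
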