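{
 "$defs": {
  "BeatModel": {
   "properties": {
    "class": {
     "enum": [
      "N",
      "S",
      "V"
     ],
     "title": "Class",
     "type": "string"
    },
    "segments": {
     "additionalProperties": {
      "maxItems": 2,
      "minItems": 2,
      "prefixItems": [
       {
        "type": "integer"
       },
       {
        "type": "integer"
       }
      ],
      "type": "array"
     },
     "propertyNames": {
      "enum": [
       "P",
       "QRS",
       "T"
      ]
     },
     "title": "Segments",
     "type": "object"
    }
   },
   "required": [
    "class",
    "segments"
   ],
   "title": "BeatModel",
   "type": "object"
  }
 },
 "properties": {
  "patient_id": {
   "title": "Patient Id",
   "type": "string"
  },
  "record_id": {
   "title": "Record Id",
   "type": "string"
  },
  "fs": {
   "exclusiveMinimum": 0,
   "title": "Fs",
   "type": "number"
  },
  "beats": {
   "items": {
    "$ref": "#/$defs/BeatModel"
   },
   "title": "Beats",
   "type": "array"
  }
 },
 "required": [
  "patient_id",
  "record_id",
  "fs",
  "beats"
 ],
 "title": "AnnotationModel",
 "type": "object"
}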