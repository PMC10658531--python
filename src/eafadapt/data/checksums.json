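{
  "table1_devices.csv": "a1d269e3abf685eee71e2fa80d94028b8bbfa57ad2f688a452526cffc4a63f38",
  "table2_patients.csv": "f79b8e01bf9cba8354c1d3dda4ae4b23bddb9b339d21fa23c5dcd6344eb0bfe9"
}
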