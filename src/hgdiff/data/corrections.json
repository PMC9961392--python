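{
  "table1": [
    {
      "row": 2,
      "field": "C1,C2",
      "as_printed": [0.0005, 0.0005],
      "corrected": [0.0050, 0.0050],
      "reason": "row labelled X1=0.500 in a series with total solute 0.010 mol dm-3; printed concentrations give total 0.001"
    }
  ],
  "table2": [
    {
      "row": 0,
      "field": "C2",
      "as_printed": 0.008,
      "corrected": 0.010,
      "reason": "the X1=0 endpoint is described in the text as a 0.0100 mol dm-3 host solution and all rows share total 0.010"
    },
    {
      "row": "all",
      "field": "X1",
      "as_printed": [0.0, 0.75, 0.5, 0.0, 1.0],
      "corrected": [0.0, 0.25, 0.5, 0.75, 1.0],
      "reason": "X1 = C1/(C1+C2) is definitional; printed column is internally inconsistent with C1, C2"
    }
  ],
  "table3": [],
  "flags": [
    {
      "quantity": "D22 at X1=0 (beta-CD binary limit)",
      "table_value": 0.436,
      "text_value": 0.460,
      "note": "fixtures carry the tabulated 0.436; the alternative text value is flagged, not used"
    },
    {
      "quantity": "EtRA4- limiting diffusivity",
      "printed": 0.384,
      "from_conductivity": 0.382,
      "note": "printed value differs by ~0.6% from R*T*lambda0/(z^2 F^2); both retained, agreement not forced"
    }
  ]
}
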