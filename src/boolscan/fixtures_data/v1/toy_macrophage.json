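{
  "name": "toy_macrophage_m1",
  "variables": [
    {
      "id": 1,
      "name": "GF",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": ""
    },
    {
      "id": 2,
      "name": "IFNG",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": ""
    },
    {
      "id": 3,
      "name": "IL10",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": ""
    },
    {
      "id": 4,
      "name": "LPS",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": ""
    },
    {
      "id": 5,
      "name": "TNFa",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": ""
    },
    {
      "id": 6,
      "name": "TLR4",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(4)"
    },
    {
      "id": 7,
      "name": "TNFR",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(5)"
    },
    {
      "id": 8,
      "name": "IFNGR",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(2)"
    },
    {
      "id": 9,
      "name": "GFR",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(1)"
    },
    {
      "id": 10,
      "name": "IL10R",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(3)"
    },
    {
      "id": 11,
      "name": "NFkB",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "max(var(6), var(7))"
    },
    {
      "id": 12,
      "name": "JAK1",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(8)"
    },
    {
      "id": 13,
      "name": "JAK2",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(8)"
    },
    {
      "id": 14,
      "name": "STAT1",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "max(var(12), var(13))"
    },
    {
      "id": 15,
      "name": "ERK",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(9)"
    },
    {
      "id": 16,
      "name": "MYC",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(15)"
    },
    {
      "id": 17,
      "name": "STAT3",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(10)"
    },
    {
      "id": 18,
      "name": "BCL2",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(11)"
    },
    {
      "id": 19,
      "name": "CASP3",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "1 - var(18)"
    },
    {
      "id": 20,
      "name": "Apoptosis_M1_macrophage",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(19)"
    },
    {
      "id": 21,
      "name": "Proliferation_M1_macrophage",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "min(var(11), var(16), 1 - var(17))"
    },
    {
      "id": 22,
      "name": "TNF_release_signal",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "var(14)"
    },
    {
      "id": 23,
      "name": "Inflammation_signal",
      "rangeFrom": 0,
      "rangeTo": 1,
      "formula": "max(var(11), var(14))"
    }
  ],
  "relationships": [
    {
      "fromVariable": 4,
      "toVariable": 6,
      "type": "Activator"
    },
    {
      "fromVariable": 5,
      "toVariable": 7,
      "type": "Activator"
    },
    {
      "fromVariable": 2,
      "toVariable": 8,
      "type": "Activator"
    },
    {
      "fromVariable": 1,
      "toVariable": 9,
      "type": "Activator"
    },
    {
      "fromVariable": 3,
      "toVariable": 10,
      "type": "Activator"
    },
    {
      "fromVariable": 6,
      "toVariable": 11,
      "type": "Activator"
    },
    {
      "fromVariable": 7,
      "toVariable": 11,
      "type": "Activator"
    },
    {
      "fromVariable": 8,
      "toVariable": 12,
      "type": "Activator"
    },
    {
      "fromVariable": 8,
      "toVariable": 13,
      "type": "Activator"
    },
    {
      "fromVariable": 12,
      "toVariable": 14,
      "type": "Activator"
    },
    {
      "fromVariable": 13,
      "toVariable": 14,
      "type": "Activator"
    },
    {
      "fromVariable": 9,
      "toVariable": 15,
      "type": "Activator"
    },
    {
      "fromVariable": 15,
      "toVariable": 16,
      "type": "Activator"
    },
    {
      "fromVariable": 10,
      "toVariable": 17,
      "type": "Activator"
    },
    {
      "fromVariable": 11,
      "toVariable": 18,
      "type": "Activator"
    },
    {
      "fromVariable": 18,
      "toVariable": 19,
      "type": "Inhibitor"
    },
    {
      "fromVariable": 19,
      "toVariable": 20,
      "type": "Activator"
    },
    {
      "fromVariable": 16,
      "toVariable": 21,
      "type": "Activator"
    },
    {
      "fromVariable": 11,
      "toVariable": 21,
      "type": "Activator"
    },
    {
      "fromVariable": 17,
      "toVariable": 21,
      "type": "Inhibitor"
    },
    {
      "fromVariable": 14,
      "toVariable": 22,
      "type": "Activator"
    },
    {
      "fromVariable": 11,
      "toVariable": 23,
      "type": "Activator"
    },
    {
      "fromVariable": 14,
      "toVariable": 23,
      "type": "Activator"
    }
  ]
}
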