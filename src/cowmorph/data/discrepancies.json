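{
  "description": "Known internal inconsistencies in the source cohort's printed tables and text. Fixtures are kept per-table; no master cohort is forced to satisfy all tables at once.",
  "items": [
    {
      "id": "t1-v2-row",
      "note": "The V2 row of the anterior-by-posterior cross-tabulation was printed with only five values and ambiguous column alignment. The shipped allocation V2 = (0,0,0,2,4,2,2,0,0,1,0) is the unique non-negative row that makes every column sum equal the posterior census vector (table5) and the row total 11 (= 106 - 95 from table2). It is documented data, not a classification rule."
    },
    {
      "id": "anterior-integral-posterior-nonintegral",
      "note": "The text reports both 1489 and 1490 cases with integral anterior but nonintegral posterior half-ring; the table1 reconstruction yields 1490."
    },
    {
      "id": "a1-variation-rate",
      "note": "The A1-variation rate is printed both as 28.18% and 28.23%; the count-derived value is 634/2246 = 28.23%."
    },
    {
      "id": "p1-side-ranksum-z",
      "note": "For the left/right P1 status distributions (2073,71,102) vs (2025,106,115) the text prints Z = 2.576 with P = 0.01. The tie-corrected rank-sum normal approximation -- the same procedure that reproduces Z = 9.944 and mean ranks 2130.10/2362.90 on the A1 side table exactly -- gives Z = 2.467, p = 0.0136 (which rounds to the printed P). 2.576 equals the two-sided p = 0.01 normal critical value, so the printed Z appears back-derived from the rounded p-value rather than computed from the counts."
    },
    {
      "id": "sec34-mild-hypoplasia-rows",
      "note": "The per-subject A1-status rows of the FTP-formation table (333 mild, 206 hypoplasia) group by developmental status, not anterior type (325 type II, 203 type III): the 11 V2 subjects are split 8 mild / 3 hypoplasia. The table therefore ships as its own fixture and is not derived from the table1 reconstruction."
    }
  ]
}
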