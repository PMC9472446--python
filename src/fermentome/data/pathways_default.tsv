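pathway	mega_pathway	function_id	is_key
starch and sucrose metabolism	carbohydrate	EC:2.4.1.34	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.86	true
starch and sucrose metabolism	carbohydrate	EC:3.2.1.20	true
starch and sucrose metabolism	carbohydrate	EC:3.2.1.28	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.26	true
starch and sucrose metabolism	carbohydrate	EC:5.4.2.6	true
starch and sucrose metabolism	carbohydrate	EC:2.4.1.5	false
starch and sucrose metabolism	carbohydrate	EC:2.7.1.4	true
starch and sucrose metabolism	carbohydrate	EC:3.2.1.58	false
starch and sucrose metabolism	carbohydrate	EC:2.7.1.2	true
starch and sucrose metabolism	carbohydrate	EC:5.3.1.9	true
starch and sucrose metabolism	carbohydrate	EC:2.4.1.25	false
starch and sucrose metabolism	carbohydrate	EC:2.4.1.1	false
starch and sucrose metabolism	carbohydrate	EC:2.4.1.11	false
starch and sucrose metabolism	carbohydrate	EC:2.7.1.1	true
starch and sucrose metabolism	carbohydrate	EC:2.4.1.8	true
starch and sucrose metabolism	carbohydrate	EC:3.2.1.10	true
starch and sucrose metabolism	carbohydrate	EC:5.4.2.2	true
starch and sucrose metabolism	carbohydrate	EC:2.7.1.196	false
starch and sucrose metabolism	carbohydrate	EC:2.4.1.15	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.93	false
starch and sucrose metabolism	carbohydrate	EC:2.7.7.9	true
starch and sucrose metabolism	carbohydrate	EC:2.4.1.18	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.1	false
starch and sucrose metabolism	carbohydrate	EC:2.4.1.64	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.21	false
starch and sucrose metabolism	carbohydrate	EC:2.4.1.12	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.54	false
starch and sucrose metabolism	carbohydrate	EC:3.1.4.1	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.4	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.3	false
starch and sucrose metabolism	carbohydrate	EC:2.7.7.27	false
starch and sucrose metabolism	carbohydrate	EC:2.4.1.9	false
starch and sucrose metabolism	carbohydrate	EC:3.2.1.122	false
starch and sucrose metabolism	carbohydrate	EC:2.4.1.21	false
starch and sucrose metabolism	carbohydrate	EC:2.4.1.7	false
pentose phosphate pathway	carbohydrate	EC:4.1.2.43	false
pentose phosphate pathway	carbohydrate	EC:2.7.1.11	true
pentose phosphate pathway	carbohydrate	EC:1.1.1.44	true
pentose phosphate pathway	carbohydrate	EC:3.1.1.31	true
pentose phosphate pathway	carbohydrate	EC:4.1.2.13	true
pentose phosphate pathway	carbohydrate	EC:2.7.1.12	false
pentose phosphate pathway	carbohydrate	EC:1.1.1.49	true
pentose phosphate pathway	carbohydrate	EC:5.4.2.7	false
pentose phosphate pathway	carbohydrate	EC:2.7.1.15	true
pentose phosphate pathway	carbohydrate	EC:5.3.1.6	true
pentose phosphate pathway	carbohydrate	EC:2.7.6.1	true
pentose phosphate pathway	carbohydrate	EC:5.1.3.1	true
pentose phosphate pathway	carbohydrate	EC:2.2.1.2	true
pentose phosphate pathway	carbohydrate	EC:2.2.1.1	true
pentose phosphate pathway	carbohydrate	EC:4.1.2.9	true
pentose phosphate pathway	carbohydrate	EC:5.3.1.27	false
pentose phosphate pathway	carbohydrate	EC:4.1.2.14	false
pentose phosphate pathway	carbohydrate	EC:2.7.1.45	false
pentose phosphate pathway	carbohydrate	EC:4.1.2.4	false
pentose phosphate pathway	carbohydrate	EC:3.1.3.11	false
pentose phosphate pathway	carbohydrate	EC:1.1.1.47	false
pentose and glucuronate interconversions	carbohydrate	EC:3.2.1.8	false
pentose and glucuronate interconversions	carbohydrate	EC:3.2.1.37	false
pentose and glucuronate interconversions	carbohydrate	EC:3.2.1.55	false
pentose and glucuronate interconversions	carbohydrate	EC:1.1.1.17	false
pyruvate metabolism	pyruvate/energy	EC:1.1.1.28	true
pyruvate metabolism	pyruvate/energy	EC:1.1.2.3	false
pyruvate metabolism	pyruvate/energy	EC:1.1.2.4	false
pyruvate metabolism	pyruvate/energy	EC:1.2.4.1	true
pyruvate metabolism	pyruvate/energy	EC:2.3.1.12	true
pyruvate metabolism	pyruvate/energy	EC:1.8.1.4	true
pyruvate metabolism	pyruvate/energy	EC:4.1.1.1	true
pyruvate metabolism	pyruvate/energy	EC:1.2.1.3	true
pyruvate metabolism	pyruvate/energy	EC:6.2.1.1	true
pyruvate metabolism	pyruvate/energy	EC:2.7.1.40	true
pyruvate metabolism	pyruvate/energy	EC:1.1.99.40	false
nitrogen metabolism	nitrogen	EC:1.4.1.2	true
nitrogen metabolism	nitrogen	EC:2.6.1.1	true
nitrogen metabolism	nitrogen	EC:2.6.1.42	true
nitrogen metabolism	nitrogen	EC:2.6.1.57	false
nitrogen metabolism	nitrogen	EC:2.6.1.58	false
nitrogen metabolism	nitrogen	EC:3.5.1.1	true
nitrogen metabolism	nitrogen	EC:3.5.3.6	true
nitrogen metabolism	nitrogen	EC:4.3.1.1	true
peptidase portfolio	peptidases	EC:3.4.11.4	false
peptidase portfolio	peptidases	EC:3.4.11.9	false
peptidase portfolio	peptidases	EC:3.4.21.96	false
stress response	stress	EC:1.1.1.67	false
stress response	stress	EC:5.4.2.2	false
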