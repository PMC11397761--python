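food_name,wholesale_price_per_kg,retail_price_per_kg
arroz pilado,2.80,3.60
fideos tallarin,3.40,4.40
avena hojuelas,4.80,6.20
harina de trigo,2.60,3.40
quinua,8.50,11.50
pan frances,4.20,5.40
azucar rubia,2.40,3.00
azucar blanca,2.60,3.20
chancaca,3.80,5.00
miel de abeja,14.00,18.00
conserva de pescado en agua,11.00,14.00
conserva de pescado en aceite,12.00,15.00
anchoveta en conserva,9.00,11.50
pollo carne,7.50,9.50
carne de res,16.00,20.00
aceite vegetal,6.80,8.40
aceite de oliva,24.00,30.00
margarina,9.50,12.00
leche evaporada entera,7.20,8.80
leche en polvo entera,22.00,28.00
queso fresco,14.00,18.00
yogur natural,5.50,7.00
lenteja,4.80,6.20
frijol canario,5.50,7.00
arveja seca partida,4.20,5.40
haba seca,4.50,5.80
garbanzo,6.00,7.60
platano de seda,1.60,2.20
naranja,1.40,2.00
manzana,2.80,3.80
mandarina,2.00,2.80
huevo de gallina,5.20,6.40
cebolla,1.20,1.80
zanahoria,1.10,1.60
tomate,1.80,2.60
zapallo,1.00,1.50
papa blanca,1.00,1.50
camote,1.10,1.60
yuca,1.30,1.90
olluco,2.00,2.80
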